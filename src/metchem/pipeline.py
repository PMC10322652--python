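"""End-to-end pipeline composition and the run manifest.

Order of stages: panel input -> fingerprints -> Tanimoto dissimilarity ->
MDS -> accuracy-maximization 2D embedding -> silhouette-selected clustering
(chemical classes) -> per-class branch modules -> eigen-metabolite summary
-> group tests -> metabocard annotation/enrichment. A run writes every
stage's tables plus a manifest (config + seed + versions + output
checksums); re-running from the same manifest reproduces the CSVs
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .clustering import cluster_dendrogram, detect_clusters
from .errors import ParameterError
from .fingerprints import FingerprintScheme
from .hmdb import ATTRIBUTE_KINDS, extract_attributes, feature_enrichment, read_cards
from .panel import read_panel, write_table
from .wmcsa import all_branches, differential_modules, wmcsa_summarize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    panel_path: str
    conc_path: str
    out_dir: str
    cards_dir: str | None = None
    fingerprint_kind: str = "morgan"
    fingerprint_radius: int = 2
    fingerprint_bits: int = 1024
    mds_dims: int = 50
    cycles: int = 20
    repeats: int = 10
    kmax: int | None = None  # None -> min(30, n - 1)
    n_classes: int = 5
    knn: int = 5
    min_module_size: int = 3
    test: str = "mannwhitney"
    alpha: float = 0.05
    impute: str = "min"
    contrast: tuple[str, str] | None = None
    seed: int = 1

    def scheme(self) -> FingerprintScheme:
        return FingerprintScheme(
            kind=self.fingerprint_kind,
            radius=self.fingerprint_radius,
            n_bits=self.fingerprint_bits,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.contrast is not None:
            d["contrast"] = list(self.contrast)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("contrast"):
            d["contrast"] = tuple(d["contrast"])
        else:
            d["contrast"] = None
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        """Write as a simple ``key = value`` config file."""
        lines = []
        for key, value in self.to_dict().items():
            if value is None:
                value = ""
            elif isinstance(value, (list, tuple)):
                value = ",".join(str(v) for v in value)
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        d: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ParameterError(f"unknown config key {key!r}")
            if raw == "":
                d[key] = None
                continue
            if key == "contrast":
                d[key] = tuple(s.strip() for s in raw.split(","))
            elif key in ("alpha",):
                d[key] = float(raw)
            elif key in ("fingerprint_radius", "fingerprint_bits", "mds_dims",
                         "cycles", "repeats", "kmax", "n_classes", "knn",
                         "min_module_size", "seed"):
                d[key] = int(raw)
            else:
                d[key] = raw
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel, conc = read_panel(config.panel_path, config.conc_path,
                             impute=config.impute)
    n_valid = len(panel.valid_names)
    if config.kmax is not None and config.kmax >= n_valid:
        # fail fast, before any fingerprint is computed
        raise ParameterError(
            f"kmax ({config.kmax}) must be smaller than the number of valid "
            f"metabolites ({n_valid})"
        )

    logger.info("stage: cluster detection (n=%d valid metabolites)", n_valid)
    assignment = detect_clusters(
        panel,
        repeats=config.repeats,
        kmax=config.kmax,
        seed=config.seed,
        scheme=config.scheme(),
        mds_dims=config.mds_dims,
        cycles=config.cycles,
        n_classes=config.n_classes,
        knn=config.knn,
    )
    write_table(assignment.to_frame(), out / "clusters.csv")
    write_table(assignment.profile.to_frame(), out / "silhouette_profile.csv")
    dist_df = pd.DataFrame(assignment.mean_distance, index=assignment.names,
                           columns=assignment.names)
    dist_df.index.name = "name"
    write_table(dist_df.reset_index(), out / "chemical_distance.csv")

    logger.info("stage: WMCSA over %d chemical classes", assignment.k_star)
    module_rows, eigen_rows, test_rows = [], [], []
    modules_by_cluster = {}
    for cid in range(1, assignment.k_star + 1):
        members = assignment.members(cid)
        if len(members) < max(2, config.min_module_size):
            logger.info("cluster %d too small for modules (%d members)", cid,
                        len(members))
            continue
        dendro = cluster_dendrogram(assignment, cid)
        (out / f"cluster_{cid}.nwk").write_text(dendro.to_newick() + "\n")
        modules = all_branches(dendro, min_size=config.min_module_size)
        if not len(modules):
            continue
        modules_by_cluster[cid] = modules
        mdf = modules.to_frame()
        mdf.insert(0, "cluster", cid)
        module_rows.append(mdf)
        E = wmcsa_summarize(conc, modules)
        edf = E.to_frame()
        edf.insert(0, "cluster", cid)
        eigen_rows.append(edf)
        if config.contrast is not None:
            tests = differential_modules(E, conc.group, config.contrast,
                                         method=config.test, alpha=config.alpha)
            tests.insert(0, "cluster", cid)
            test_rows.append(tests)
    if module_rows:
        write_table(pd.concat(module_rows, ignore_index=True), out / "modules.csv")
        write_table(pd.concat(eigen_rows, ignore_index=True),
                    out / "eigen_metabolites.csv")
    if test_rows:
        write_table(pd.concat(test_rows, ignore_index=True),
                    out / "module_tests.csv")

    if config.cards_dir is not None and modules_by_cluster:
        logger.info("stage: metabocard annotation")
        cards = read_cards(config.cards_dir)
        universe = set(panel.valid_names)
        enr_rows = []
        for kind in ATTRIBUTE_KINDS:
            table = extract_attributes(cards, kind, panel=panel)
            table.mapping = {k: v for k, v in table.mapping.items()
                             if k in universe}
            for cid, modules in modules_by_cluster.items():
                enr = feature_enrichment(modules, table, universe)
                if len(enr):
                    enr.insert(0, "cluster", cid)
                    enr_rows.append(enr)
        if enr_rows:
            write_table(pd.concat(enr_rows, ignore_index=True),
                        out / "enrichment.csv")

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "metchem": __version__,
            "python": platform.python_version(),
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in (".csv", ".nwk")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete: %s", out)
    return out


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Re-run a pipeline from a manifest; ``out_dir`` overrides the output
    directory (the manifest's config otherwise overwrites in place)."""
    manifest = json.loads(Path(manifest_path).read_text())
    config = RunConfig.from_dict(manifest["config"])
    if out_dir is not None:
        config.out_dir = str(out_dir)
    return run_pipeline(config)
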