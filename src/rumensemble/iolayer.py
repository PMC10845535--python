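"""Readers, writers, configuration, and the end-to-end pipeline.

On-disk conventions: count tables are TSV with taxa as rows and the taxon
id in the first column, accompanied by a taxonomy sidecar TSV mapping each
taxon to its semicolon-separated phylum;class;order;family;genus lineage.
Cow tables are one-row-per-cow CSV.  A minimal BIOM 1.0 (JSON) round trip
is provided for interoperability.  All pipeline randomness flows from one
global seed through named per-stage substreams, and every run writes a
manifest with SHA-256 hashes of its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import methane as methane_mod
from .ensemble import export_vote_network, run_ensemble
from .features import build_feature_matrix
from .mlpredict import cv_feature_select, sign_confusion
from .simdata import RANKS, CountTable, SimConfig, generate_cohort
from .traits import compute_traits

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# count table round trip


def write_count_table(table: CountTable, counts_path, taxonomy_path) -> None:
    df = table.counts.copy()
    df.index.name = "taxon"
    df.to_csv(counts_path, sep="\t")
    lineage = table.lineages.apply(
        lambda row: ";".join(row[r] for r in RANKS), axis=1)
    pd.DataFrame({"taxon": table.lineages.index, "lineage": lineage.values}) \
        .to_csv(taxonomy_path, sep="\t", index=False)


def read_count_table(counts_path, taxonomy_path) -> CountTable:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate taxon ids in count table")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError("non-integer counts")
        df = df.round().astype(np.int64)
    tax = pd.read_csv(taxonomy_path, sep="\t")
    if tax["taxon"].duplicated().any():
        raise ValueError("duplicate taxon ids in taxonomy")
    split = tax["lineage"].str.split(";")
    bad = split.map(len) != len(RANKS)
    if bad.any():
        raise ValueError(
            f"incomplete lineage for taxon {tax.loc[bad, 'taxon'].iloc[0]!r}")
    lineages = pd.DataFrame(split.tolist(), columns=list(RANKS),
                            index=pd.Index(tax["taxon"], name="taxon"))
    missing = set(df.index) - set(lineages.index)
    if missing:
        raise ValueError(f"taxa without taxonomy entry: {sorted(missing)[:5]}")
    table = CountTable(df.astype(np.int64), lineages.loc[df.index])
    table.validate()
    return table


def write_biom(table: CountTable, path) -> None:
    """Minimal BIOM 1.0 JSON export (dense matrix)."""
    doc = {
        "id": None, "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table", "generated_by": "rumensemble",
        "matrix_type": "dense", "matrix_element_type": "int",
        "shape": list(table.counts.shape),
        "rows": [{"id": t, "metadata": {"taxonomy":
                                        list(table.lineages.loc[t, list(RANKS)])}}
                 for t in table.counts.index],
        "columns": [{"id": s, "metadata": None} for s in table.counts.columns],
        "data": table.counts.to_numpy().tolist(),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_biom(path) -> CountTable:
    doc = json.loads(Path(path).read_text())
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    counts = pd.DataFrame(np.asarray(doc["data"], dtype=np.int64),
                          index=pd.Index(taxa, name="taxon"), columns=samples)
    lineages = pd.DataFrame(
        [r["metadata"]["taxonomy"] for r in doc["rows"]],
        columns=list(RANKS), index=pd.Index(taxa, name="taxon"))
    table = CountTable(counts, lineages)
    table.validate()
    return table


def write_cow_table(cows: pd.DataFrame, path) -> None:
    cows.to_csv(path, index=False)


def read_cow_table(path) -> pd.DataFrame:
    cows = pd.read_csv(path)
    return cows.set_index("cow_id", drop=False)


# ---------------------------------------------------------------------------
# configuration and pipeline


@dataclass
class PipelineConfig:
    """Paths and parameters for :func:`run_pipeline`."""

    outdir: str = "rumensemble_out"
    counts_path: str | None = None      # None -> simulate
    taxonomy_path: str | None = None
    cows_path: str | None = None
    trait: str = "RFI"
    seed: int = 0
    folds: int = 10
    lambda_grid: tuple = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
    max_features: int = 50
    pseudocount: float = 0.5
    n_extreme: int = 50
    min_votes: int = 4
    min_prevalence: float = 0.10
    vote_granularity: str = "method_x_representation"
    sim: dict = field(default_factory=dict)   # overrides for SimConfig

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.counts_path, self.taxonomy_path, self.cows_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.trait not in ("RFI", "residual_MFE", "residual_MPE"):
            raise ValueError(f"unknown trait {self.trait!r}")
        if not 0 < self.min_prevalence < 1 and self.min_prevalence != 0:
            raise ValueError("min_prevalence must lie in [0, 1)")


def stage_seed(seed: int, stage: str) -> int:
    """Named, stable substream seed below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate/load -> traits -> features -> predict -> ensemble ->
    methane, writing every stage output plus a hash manifest to ``outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def _stage(name):
        log.info("stage: %s", name)

    _stage("input")
    if config.counts_path is None:
        sim_kwargs = dict(config.sim)
        sim_kwargs["seed"] = stage_seed(config.seed, "simulate")
        sim_config = SimConfig(**sim_kwargs)
        cows, counts, truth = generate_cohort(sim_config)
        write_cow_table(cows, outdir / "cows.csv")
        write_count_table(counts, outdir / "counts.tsv", outdir / "taxonomy.tsv")
        (outdir / "ground_truth.json").write_text(
            json.dumps(truth.to_dict(), sort_keys=True))
        outputs.update({"cows": outdir / "cows.csv",
                        "counts": outdir / "counts.tsv",
                        "taxonomy": outdir / "taxonomy.tsv",
                        "ground_truth": outdir / "ground_truth.json"})
    else:
        counts = read_count_table(config.counts_path, config.taxonomy_path)
        cows = read_cow_table(config.cows_path)

    _stage("traits")
    traits, reports = compute_traits(cows)
    traits.to_csv(outdir / "traits.csv", index=False)
    (outdir / "trait_models.json").write_text(
        json.dumps(_jsonable(reports), sort_keys=True))
    outputs["traits"] = outdir / "traits.csv"
    outputs["trait_models"] = outdir / "trait_models.json"

    _stage("features")
    fm = build_feature_matrix(counts, pseudocount=config.pseudocount)
    fm.values.to_csv(outdir / "features.tsv", sep="\t")
    (outdir / "feature_provenance.json").write_text(
        json.dumps({k: list(v) for k, v in fm.provenance.items()},
                   sort_keys=True))
    outputs["features"] = outdir / "features.tsv"
    outputs["feature_provenance"] = outdir / "feature_provenance.json"

    _stage("predict")
    y = traits[config.trait]
    report = cv_feature_select(
        fm.values.loc[y.index], y, k_folds=config.folds,
        lambda_grid=config.lambda_grid,
        seed=stage_seed(config.seed, "predict"),
        max_features=config.max_features)
    confusion = sign_confusion(y, report.oof_predictions)
    prediction = {
        "trait": config.trait,
        "selected": report.selected, "lambdas": report.lambdas,
        "mse": report.mse, "rmse": report.rmse, "r2": report.r2,
        "fold_mse": report.fold_mse,
        "confusion": {"tp": confusion.tp, "tn": confusion.tn,
                      "fp": confusion.fp, "fn": confusion.fn,
                      "precision": confusion.precision,
                      "recall": confusion.recall, "f1": confusion.f1},
    }
    (outdir / "prediction.json").write_text(
        json.dumps(_jsonable(prediction), sort_keys=True))
    report.oof_predictions.rename("predicted").to_frame().to_csv(
        outdir / "predictions.csv")
    outputs["prediction"] = outdir / "prediction.json"
    outputs["predictions"] = outdir / "predictions.csv"

    _stage("ensemble")
    higher = config.trait != "RFI"
    consensus = run_ensemble(
        counts, y, n_extreme=config.n_extreme, min_votes=config.min_votes,
        higher_is_efficient=higher,
        seed=stage_seed(config.seed, "ensemble"),
        min_prevalence=config.min_prevalence,
        pseudocount=config.pseudocount,
        vote_granularity=config.vote_granularity)
    consensus.table.to_csv(outdir / "consensus.tsv", sep="\t")
    edges, nodes = export_vote_network(consensus)
    edges.to_csv(outdir / "vote_network_edges.tsv", sep="\t", index=False)
    nodes.to_csv(outdir / "vote_network_nodes.tsv", sep="\t", index=False)
    outputs["consensus"] = outdir / "consensus.tsv"
    outputs["vote_network_edges"] = outdir / "vote_network_edges.tsv"
    outputs["vote_network_nodes"] = outdir / "vote_network_nodes.tsv"

    _stage("methane")
    data = methane_mod.add_methane_columns(cows, traits)
    data["microbiome_predicted"] = report.oof_predictions
    comparisons = {}
    for criterion, flip in (("RFI", False), ("microbiome_predicted", False),
                            ("residual_MFE", True), ("residual_MPE", True)):
        rep = methane_mod.selection_comparison(
            data, criterion, n_each=config.n_extreme, higher_is_efficient=flip)
        comparisons[criterion] = rep.table.to_dict(orient="index")
    if "genomic_pta_rfi" in cows.columns:
        data["genomic_pta_rfi"] = cows["genomic_pta_rfi"]
        rep = methane_mod.selection_comparison(
            data, "genomic_pta_rfi", n_each=config.n_extreme)
        comparisons["genomic_pta_rfi"] = rep.table.to_dict(orient="index")
    (outdir / "methane.json").write_text(
        json.dumps(_jsonable(comparisons), sort_keys=True))
    outputs["methane"] = outdir / "methane.json"

    manifest = {
        "seed": config.seed,
        "parameters": _jsonable(dataclasses.asdict(config)),
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ("simulate", "predict", "ensemble")},
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)}
                    for k, v in outputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True,
                                                     indent=2))
    return manifest
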