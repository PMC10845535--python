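"""Feature engineering for microbiome-based trait prediction.

A genus-level count table is expanded into the engineered predictor matrix:
counts collapsed to each of the five taxonomy ranks (phylum through genus),
each rank expressed in three representations (raw count, relative abundance
in percent, centered log-ratio), plus 22 alpha-diversity indices computed
once at the leaf (genus) level.  Feature ids encode their provenance as
``rank|taxon|representation`` and ``diversity|index``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simdata import RANKS, CountTable

REPRESENTATIONS = ("count", "relabund", "clr")

DEFAULT_PSEUDOCOUNT = 0.5

#: relative-abundance cutoff (fraction) for the core/low/rare partitions
ABUNDANCE_CUTOFF = 0.002


def collapse_taxonomy(counts: CountTable, rank: str) -> CountTable:
    """Sum genus-level counts to a coarser rank; column sums are preserved."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if rank == "genus":
        return CountTable(counts.counts.copy(), counts.lineages.copy())
    labels = counts.lineages.loc[counts.counts.index, rank]
    if labels.isna().any():
        raise ValueError(f"incomplete lineages at rank {rank}")
    collapsed = counts.counts.groupby(labels.values).sum()
    collapsed.index.name = "taxon"
    upto = RANKS[:RANKS.index(rank) + 1]
    lineages = (counts.lineages.groupby(labels.values).first()[list(upto)])
    lineages.index.name = "taxon"
    return CountTable(collapsed, lineages)


def relative_abundance(counts) -> pd.DataFrame:
    """Percent relative abundance per sample (columns sum to 100)."""
    mat = counts.counts if isinstance(counts, CountTable) else counts
    totals = mat.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("empty sample")
    return 100.0 * mat / totals


def clr_transform(counts, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Centered log-ratio: ln((x + c) / geometric mean of (x + c)) per sample."""
    mat = counts.counts if isinstance(counts, CountTable) else counts
    x = np.asarray(mat, float) + pseudocount
    if (x <= 0).any():
        raise ValueError("zero counts require a positive pseudocount")
    logx = np.log(x)
    out = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


# ---------------------------------------------------------------------------
# alpha diversity: 22 indices per sample
#
# Each index is its own function taking the raw count vector of one sample
# (and where needed table-wide context), so alternates can be swapped.

def _props(x: np.ndarray) -> np.ndarray:
    return x / x.sum()


def observed(x):
    return float((x > 0).sum())


def chao1(x):
    s = (x > 0).sum()
    f1 = (x == 1).sum()
    f2 = (x == 2).sum()
    return float(s + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def inverse_simpson(x):
    p = _props(x)
    return float(1.0 / (p ** 2).sum())


def gini_simpson(x):
    p = _props(x)
    return float(1.0 - (p ** 2).sum())


def shannon(x):
    p = _props(x)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def fisher_alpha(x):
    """Fisher's alpha solving S = alpha * ln(1 + N / alpha)."""
    s, n = float((x > 0).sum()), float(x.sum())
    if s <= 0 or n <= 0:
        raise ValueError("empty sample")
    if s == 1:
        return 0.0

    def f(a):
        return a * np.log1p(n / a) - s

    return float(optimize.brentq(f, 1e-12, 1e9, xtol=1e-12, rtol=1e-14))


def coverage(x, threshold: float = 0.5):
    """Minimal number of taxa whose summed abundance reaches the threshold."""
    p = np.sort(_props(x))[::-1]
    return float(np.searchsorted(np.cumsum(p), threshold - 1e-12) + 1)


def camargo_evenness(x):
    """1 - sum_{i<j} |p_i - p_j| / S over observed taxa."""
    p = np.sort(_props(x)[x > 0])
    s = len(p)
    k = np.arange(s)
    pairdiff = float((p * (2 * k - s + 1)).sum())
    return float(1.0 - pairdiff / s)


def pielou_evenness(x):
    s = (x > 0).sum()
    if s <= 1:
        return 0.0
    return float(shannon(x) / np.log(s))


def simpson_evenness(x):
    return float(inverse_simpson(x) / (x > 0).sum())


def evar_evenness(x):
    """1 - (2/pi) arctan(variance of ln counts over observed taxa)."""
    v = np.log(x[x > 0]).var()
    return float(1.0 - (2.0 / np.pi) * np.arctan(v))


def bulla_evenness(x):
    p = _props(x)[x > 0]
    s = len(p)
    if s <= 1:
        return 0.0
    o = np.minimum(p, 1.0 / s).sum()
    return float((o - 1.0 / s) / (1.0 - 1.0 / s))


def dominance_dbp(x):
    """Berger-Parker: relative abundance of the single most abundant taxon."""
    return float(_props(x).max())


def dominance_dmn(x):
    """Summed relative abundance of the two most abundant taxa."""
    p = np.sort(_props(x))[::-1]
    return float(p[:2].sum())


def dominance_absolute(x):
    return float(x.max())


def dominance_relative(x):
    return float(_props(x).max())


def dominance_simpson(x):
    p = _props(x)
    return float((p ** 2).sum())


def dominance_gini(x):
    """Gini index of the relative-abundance distribution over all taxa."""
    p = np.sort(_props(x))
    s = len(p)
    k = np.arange(1, s + 1)
    return float((2 * k - s - 1) @ p / s)


def core_abundance(x, core_mask: np.ndarray):
    """Summed relative abundance of the table-wide core taxa.

    Core taxa: relative abundance above 0.2% in more than half the samples.
    """
    return float(_props(x)[core_mask].sum())


def rarity_low_abundance(x):
    """Summed relative abundance of taxa below 0.2% in this sample."""
    p = _props(x)
    return float(p[p < ABUNDANCE_CUTOFF].sum())


def rarity_rare_abundance(x, core_mask: np.ndarray):
    return float(1.0 - core_abundance(x, core_mask))


def rarity_log_modulo_skewness(x, n_bins: int = 50):
    """ln(|skewness| + 1) of the binned abundance distribution (50 bins)."""
    p = _props(x)[x > 0]
    if len(p) < 2 or p.max() == p.min():
        return 0.0
    hist, _ = np.histogram(p, bins=n_bins, range=(p.min(), p.max()))
    return float(np.log(abs(stats.skew(hist)) + 1.0))


#: the 22 indices in their canonical column order
DIVERSITY_INDICES = (
    "observed", "chao1", "diversity_inverse_simpson", "diversity_gini_simpson",
    "diversity_shannon", "diversity_fisher", "diversity_coverage",
    "evenness_camargo", "evenness_pielou", "evenness_simpson", "evenness_evar",
    "evenness_bulla", "dominance_dbp", "dominance_dmn", "dominance_absolute",
    "dominance_relative", "dominance_simpson", "dominance_core_abundance",
    "dominance_gini", "rarity_log_modulo_skewness", "rarity_low_abundance",
    "rarity_rare_abundance",
)


def core_taxon_mask(counts) -> np.ndarray:
    """Taxa with relative abundance > 0.2% in more than 50% of samples."""
    mat = counts.counts if isinstance(counts, CountTable) else counts
    ra = np.asarray(mat, float) / np.asarray(mat.sum(axis=0), float)
    return (ra > ABUNDANCE_CUTOFF).mean(axis=1) > 0.5


def alpha_diversity(counts) -> pd.DataFrame:
    """All 22 alpha-diversity indices, one row per sample."""
    mat = counts.counts if isinstance(counts, CountTable) else counts
    if (mat.sum(axis=0) <= 0).any():
        raise ValueError("empty sample")
    core_mask = core_taxon_mask(mat)
    simple = {
        "observed": observed, "chao1": chao1,
        "diversity_inverse_simpson": inverse_simpson,
        "diversity_gini_simpson": gini_simpson,
        "diversity_shannon": shannon, "diversity_fisher": fisher_alpha,
        "diversity_coverage": coverage, "evenness_camargo": camargo_evenness,
        "evenness_pielou": pielou_evenness, "evenness_simpson": simpson_evenness,
        "evenness_evar": evar_evenness, "evenness_bulla": bulla_evenness,
        "dominance_dbp": dominance_dbp, "dominance_dmn": dominance_dmn,
        "dominance_absolute": dominance_absolute,
        "dominance_relative": dominance_relative,
        "dominance_simpson": dominance_simpson,
        "dominance_gini": dominance_gini,
        "rarity_log_modulo_skewness": rarity_log_modulo_skewness,
        "rarity_low_abundance": rarity_low_abundance,
    }
    rows = {}
    values = np.asarray(mat, float)
    for j, sample in enumerate(mat.columns):
        x = values[:, j]
        row = {name: fn(x) for name, fn in simple.items()}
        row["dominance_core_abundance"] = core_abundance(x, core_mask)
        row["rarity_rare_abundance"] = rarity_rare_abundance(x, core_mask)
        rows[sample] = row
    return pd.DataFrame.from_dict(rows, orient="index")[list(DIVERSITY_INDICES)]


# ---------------------------------------------------------------------------
# assembled feature matrix


@dataclass
class FeatureMatrix:
    """Cows x features with per-feature provenance."""

    values: pd.DataFrame                  # index: cow ids, columns: feature ids
    provenance: dict                      # feature id -> (rank, taxon, repr)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)


def build_feature_matrix(counts: CountTable,
                         pseudocount: float = DEFAULT_PSEUDOCOUNT,
                         include_diversity: bool = True) -> FeatureMatrix:
    """Engineered predictors: 5 ranks x 3 representations + diversity.

    Feature count = 3 * (total taxa across ranks) + 22 when the diversity
    block is enabled.
    """
    counts.validate()
    blocks, provenance = [], {}
    for rank in RANKS:
        table = collapse_taxonomy(counts, rank)
        reps = {
            "count": table.counts.astype(float),
            "relabund": relative_abundance(table),
            "clr": clr_transform(table, pseudocount),
        }
        for rep in REPRESENTATIONS:
            block = reps[rep].T
            block.columns = [f"{rank}|{t}|{rep}" for t in block.columns]
            for col, taxon in zip(block.columns, reps[rep].index):
                provenance[col] = (rank, taxon, rep)
            blocks.append(block)
    if include_diversity:
        div = alpha_diversity(counts)
        div.columns = [f"diversity|{c}" for c in div.columns]
        for col in div.columns:
            provenance[col] = ("diversity", col.split("|", 1)[1], "index")
        blocks.append(div)
    values = pd.concat(blocks, axis=1)
    if values.columns.duplicated().any():
        dupe = values.columns[values.columns.duplicated()][0]
        raise ValueError(f"duplicate feature id {dupe!r}")
    if values.isna().values.any():
        raise ValueError("missing values in feature matrix")
    values.index.name = "cow_id"
    return FeatureMatrix(values, provenance)
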