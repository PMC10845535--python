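"""Synthetic cohort generator: cows, rumen count tables, and planted truth.

The generator emulates a multi-site lactating-cow feed-efficiency study: a
few hundred Holstein cows spread over several experiments and treatments,
each with daily dry matter intake (DMI), body weight, body condition score,
milk component yields, and a genus-level 16S count table with overdispersed
compositional counts.  Dry matter intake follows a linear energy-sink model

    DMI = b0 + b_parity*multiparous + b_MBW*MBW + b_BEC*BEC + b_NESec*NESec
          + cohort + microbiome + noise

whose residual (the RFI) carries a configurable microbiome-driven variance
fraction, realized through planted taxa whose log-abundance tracks a latent
per-cow score.  Everything planted is recorded in a :class:`GroundTruth`
object so downstream recovery can be tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

RANKS = ("phylum", "class", "order", "family", "genus")

#: traits that can receive planted microbiome effects
PLANTABLE_TRAITS = ("RFI", "residual_MFE", "residual_MPE")

# Net-energy-secreted coefficients (Mcal per kg of component)
NESEC_FAT, NESEC_PROTEIN, NESEC_LACTOSE = 9.29, 5.47, 3.95


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Configuration for :func:`generate_cohort`.

    Defaults reproduce the study conditions: 454 cows in 6 experiments and
    19 treatments; covariate means/SDs of the experimental summary table
    (DMI 22.6 +- 2.60 kg/d, NESec 27.1 +- 4.20 Mcal/d, MBW 127 +- 9.70
    kg^0.75, BEC 2.60 +- 3.20 Mcal/d); DMI model coefficients
    (parity 0.87, MBW 0.09, BEC 0.17, NESec 0.37); cohort R-squared 0.07 and
    residual (RFI) share 0.19 of DMI variance; and a 0.36 microbiome
    fraction of the RFI variance.
    """

    n_cows: int = 454
    n_experiments: int = 6
    n_treatments_total: int = 19
    # taxa per rank, coarse to fine; each finer rank must have >= taxa
    taxonomy_shape: dict = field(default_factory=lambda: {
        "phylum": 8, "class": 14, "order": 24, "family": 48, "genus": 150})
    library_size_mean: float = 20_000.0
    library_size_dispersion: float = 0.3   # lognormal sigma of read depths
    dispersion: float = 1.0                # sample-to-sample log-abundance SD
    baseline_log_sd: float = 2.0           # spread of taxon mean log-abundances
    covariate_means: dict = field(default_factory=lambda: {
        "NESec": 27.1, "MBW": 127.0, "BEC": 2.60, "BCS": 3.0, "DMI": 22.6})
    covariate_sds: dict = field(default_factory=lambda: {
        "NESec": 4.20, "MBW": 9.70, "BEC": 3.20, "BCS": 0.40})
    multiparous_fraction: float = 233 / 454
    # milk composition (% of milk) used to allocate NESec into component yields
    milk_fat_pct: float = 3.55
    milk_protein_pct: float = 3.05
    milk_lactose_pct: float = 4.75
    # diet composition per experiment drawn around these (% of DM)
    diet_fatty_acid_pct: float = 4.64     # ether extract used as proxy
    diet_fatty_acid_sd: float = 1.2
    diet_ndf_pct: float = 28.6
    diet_ndf_sd: float = 3.5
    dmi_coefficients: dict = field(default_factory=lambda: {
        "parity": 0.87, "MBW": 0.09, "BEC": 0.17, "NESec": 0.37})
    cohort_r2: float = 0.07               # treatment-within-experiment share
    rfi_variance_share: float = 0.19      # residual share of DMI variance
    microbiome_variance_fraction: dict = field(default_factory=lambda: {
        "RFI": 0.36, "residual_MFE": 0.57, "residual_MPE": 0.48})
    # residual SDs (g/kg DMI) of the gross-efficiency traits before modelling
    mfe_residual_sd: float = 4.0
    mpe_residual_sd: float = 3.0
    n_planted_taxa: dict = field(default_factory=lambda: {
        "RFI": 5, "residual_MFE": 5, "residual_MPE": 5})
    planted_effect_size: float = 2.0      # log/CLR shift per SD of cow signal
    pta_correlation: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_cows <= 0:
            raise SimulationError("n_cows must be positive")
        if self.n_treatments_total < self.n_experiments:
            raise SimulationError("need at least one treatment per experiment")
        for trait, f in self.microbiome_variance_fraction.items():
            if not 0 <= f < 1:
                raise SimulationError(
                    f"variance fraction for {trait} must be in [0, 1)")
        if not 0 <= self.cohort_r2 + self.rfi_variance_share < 1:
            raise SimulationError("cohort_r2 + rfi_variance_share must be < 1")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be non-negative")
        shape = [self.taxonomy_shape[r] for r in RANKS]
        if any(a > b for a, b in zip(shape, shape[1:])):
            raise SimulationError("each finer rank needs >= taxa than its parent")
        if self.library_size_mean < 3000:
            warnings.warn(
                "library_size_mean below the 3000-read inclusion depth",
                UserWarning)


@dataclass
class CountTable:
    """Genus-level taxa x samples integer counts with full lineages."""

    counts: pd.DataFrame            # taxa x samples, int
    lineages: pd.DataFrame          # indexed by taxon id, columns = RANKS

    @property
    def taxon_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    def validate(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every sample needs a positive read count")
        missing = set(self.counts.index) - set(self.lineages.index)
        if missing:
            raise ValueError(f"taxa without lineage: {sorted(missing)[:5]}")
        incomplete = self.lineages.loc[self.counts.index, list(RANKS)].isna()
        if incomplete.values.any():
            bad = self.lineages.index[incomplete.any(axis=1)][0]
            raise ValueError(f"incomplete lineage for taxon {bad}")


@dataclass
class GroundTruth:
    """Everything the simulator planted, for recovery tests."""

    planted_taxa: dict              # trait -> list of genus ids
    effect_sizes: dict              # trait -> np.ndarray
    planted_scores: dict            # trait -> per-cow standardized score
    true_dmi_coefficients: dict     # incl. intercept
    true_cohort_effects: dict       # treatment id -> effect (kg/d DMI)
    true_microbiome_variance_fraction: dict
    true_rfi: np.ndarray            # per-cow DMI residual (microbiome + noise)
    true_pta: np.ndarray            # per-cow genomic PTA for RFI (standardized)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("true_rfi", "true_pta"):
            d[key] = np.asarray(d[key]).tolist()
        d["effect_sizes"] = {k: np.asarray(v).tolist()
                             for k, v in d["effect_sizes"].items()}
        d["planted_scores"] = {k: np.asarray(v).tolist()
                               for k, v in d["planted_scores"].items()}
        return d


# ---------------------------------------------------------------------------
# taxonomy and counts


def build_taxonomy(shape: dict, rng: np.random.Generator) -> pd.DataFrame:
    """Random nested 5-rank taxonomy; every parent gets >= 1 child."""
    labels = {}
    for rank in RANKS:
        n = int(shape[rank])
        width = len(str(n))
        labels[rank] = [f"{rank.capitalize()}_{i + 1:0{width}d}" for i in range(n)]
    parent_of = {}
    for coarse, fine in zip(RANKS, RANKS[1:]):
        n_par, n_child = len(labels[coarse]), len(labels[fine])
        # first cover every parent once, then attach the rest at random
        assignment = list(range(n_par)) + list(rng.integers(0, n_par,
                                                            n_child - n_par))
        order = rng.permutation(n_child)
        parent_of[fine] = {labels[fine][c]: labels[coarse][assignment[j]]
                           for j, c in enumerate(order)}
    rows = []
    for genus in labels["genus"]:
        lineage = {"genus": genus}
        child = genus
        for rank in ("family", "order", "class"):
            child = parent_of[RANKS[RANKS.index(rank) + 1]][child]
            lineage[rank] = child
        lineage["phylum"] = parent_of["class"][lineage["class"]]
        rows.append(lineage)
    df = pd.DataFrame(rows).set_index(pd.Index(labels["genus"], name="taxon"))
    return df[list(RANKS)]


def _simulate_counts(config: SimConfig, rng: np.random.Generator,
                     shifts: np.ndarray | None,
                     sample_ids: list) -> tuple[CountTable, np.ndarray]:
    """Log-normal abundances + multinomial sampling.

    Returns the count table and the true centered log-abundance matrix
    (taxa x samples), i.e. the CLR of the underlying composition.
    """
    n_taxa = config.taxonomy_shape["genus"]
    n = len(sample_ids)
    lineages = build_taxonomy(config.taxonomy_shape, rng)
    mu = rng.normal(0.0, config.baseline_log_sd, n_taxa)
    log_abund = mu[:, None] + rng.normal(0.0, config.dispersion, (n_taxa, n))
    if shifts is not None:
        log_abund = log_abund + shifts
    true_clr = log_abund - log_abund.mean(axis=0, keepdims=True)
    # compositional closure happens only here, at sampling
    p = np.exp(log_abund - log_abund.max(axis=0, keepdims=True))
    p /= p.sum(axis=0, keepdims=True)
    sigma = config.library_size_dispersion
    mu_log = np.log(max(config.library_size_mean, 1.0)) - sigma ** 2 / 2
    depths = np.maximum(3000, np.round(rng.lognormal(mu_log, sigma, n))).astype(int)
    counts = rng.multinomial(depths, p.T).T
    table = CountTable(
        counts=pd.DataFrame(counts, index=lineages.index.copy(),
                            columns=sample_ids),
        lineages=lineages)
    return table, true_clr


def generate_counts(config: SimConfig,
                    cow_signal: np.ndarray | None = None,
                    planted_taxa: list | None = None,
                    effect_sizes: np.ndarray | None = None,
                    rng: np.random.Generator | None = None) -> CountTable:
    """Generate a count table, optionally with planted differential taxa.

    ``cow_signal`` is a per-sample score; the planted taxa's log-abundance
    is shifted by ``effect_size * cow_signal``.  If ``planted_taxa`` is not
    given, the first ``n_planted_taxa['RFI']`` genera (by rng choice) are
    used with ``config.planted_effect_size``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cows if cow_signal is None else len(cow_signal)
    sample_ids = [f"cow_{i + 1:04d}" for i in range(n)]
    shifts = None
    if cow_signal is not None:
        n_taxa = config.taxonomy_shape["genus"]
        if planted_taxa is None:
            k = config.n_planted_taxa.get("RFI", 0)
            idx = rng.choice(n_taxa, size=k, replace=False)
        else:
            idx = np.asarray(planted_taxa, dtype=int)
        if effect_sizes is None:
            effect_sizes = np.full(len(idx), config.planted_effect_size)
        shifts = np.zeros((n_taxa, n))
        shifts[idx] = np.outer(effect_sizes, np.asarray(cow_signal, float))
    table, _ = _simulate_counts(config, rng, shifts, sample_ids)
    return table


# ---------------------------------------------------------------------------
# cohort generation


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _fixed_effect_variance(config: SimConfig) -> float:
    b = config.dmi_coefficients
    p = config.multiparous_fraction
    return (b["parity"] ** 2 * p * (1 - p)
            + b["MBW"] ** 2 * config.covariate_sds["MBW"] ** 2
            + b["BEC"] ** 2 * config.covariate_sds["BEC"] ** 2
            + b["NESec"] ** 2 * config.covariate_sds["NESec"] ** 2)


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, CountTable, GroundTruth]:
    """Simulate cows, microbiome counts, and the planted ground truth.

    Returns a cow table (one row per cow), a genus-level count table with
    matching sample ids, and the :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cows
    cow_ids = [f"cow_{i + 1:04d}" for i in range(n)]

    # --- cohort structure: treatments nested in experiments -----------------
    n_exp, n_trt = config.n_experiments, config.n_treatments_total
    trt_exp = np.sort(np.concatenate([np.arange(n_exp),
                                      rng.integers(0, n_exp, n_trt - n_exp)]))
    treatment_of_cow = rng.permutation(np.arange(n) % n_trt)
    experiment_of_cow = trt_exp[treatment_of_cow]
    trt_ids = [f"trt_{t + 1:02d}" for t in range(n_trt)]
    exp_ids = [f"exp_{e + 1}" for e in range(n_exp)]

    # --- covariates ----------------------------------------------------------
    means, sds = config.covariate_means, config.covariate_sds
    parity = (rng.random(n) < config.multiparous_fraction).astype(int)
    mbw = np.clip(rng.normal(means["MBW"], sds["MBW"], n), 60.0, None)
    bw = mbw ** (4.0 / 3.0)
    bcs = np.clip(np.round(rng.normal(means["BCS"], sds["BCS"], n) * 4) / 4,
                  1.0, 5.0)
    bec = rng.normal(means["BEC"], sds["BEC"], n)
    bw_change = bec / (2.88 + 1.036 * bcs)
    nesec_target = np.clip(rng.normal(means["NESec"], sds["NESec"], n), 5.0, None)
    fat_pct = np.clip(rng.normal(config.milk_fat_pct, 0.30, n), 1.5, None)
    protein_pct = np.clip(rng.normal(config.milk_protein_pct, 0.15, n), 1.5, None)
    lactose_pct = np.clip(rng.normal(config.milk_lactose_pct, 0.15, n), 3.0, None)
    energy_per_kg_milk = (NESEC_FAT * fat_pct + NESEC_PROTEIN * protein_pct
                          + NESEC_LACTOSE * lactose_pct) / 100.0
    milk_kg = nesec_target / energy_per_kg_milk
    fat_kg = milk_kg * fat_pct / 100.0
    protein_kg = milk_kg * protein_pct / 100.0
    lactose_kg = milk_kg * lactose_pct / 100.0

    # --- planted microbiome taxa and latent cow factors ---------------------
    n_taxa = config.taxonomy_shape["genus"]
    total_planted = sum(config.n_planted_taxa.get(t, 0) for t in PLANTABLE_TRAITS)
    if total_planted > n_taxa:
        raise SimulationError("more planted taxa than genera")
    drawn = rng.choice(n_taxa, size=total_planted, replace=False)
    planted_idx, effect_sizes, factors = {}, {}, {}
    offset = 0
    for trait in PLANTABLE_TRAITS:
        k = config.n_planted_taxa.get(trait, 0)
        planted_idx[trait] = drawn[offset:offset + k]
        effect_sizes[trait] = np.full(k, config.planted_effect_size)
        factors[trait] = rng.standard_normal(n)
        offset += k
    shifts = np.zeros((n_taxa, n))
    for trait in PLANTABLE_TRAITS:
        shifts[planted_idx[trait]] += np.outer(effect_sizes[trait],
                                               factors[trait])
    counts, true_clr = _simulate_counts(config, rng, shifts, cow_ids)
    # the planted per-cow score is what downstream CLR features can recover
    scores = {}
    for trait in PLANTABLE_TRAITS:
        idx = planted_idx[trait]
        if len(idx):
            raw = effect_sizes[trait] @ true_clr[idx]
            scores[trait] = _standardize(raw)
        else:
            scores[trait] = np.zeros(n)

    fracs = config.microbiome_variance_fraction

    # --- milk-side planted effects (residual MFE / MPE), then final NESec ---
    def _residual(trait: str, sd: float) -> np.ndarray:
        f = fracs.get(trait, 0.0)
        return sd * (np.sqrt(f) * scores[trait]
                     + np.sqrt(1 - f) * rng.standard_normal(n))

    # milk-side cohort effects keep the same cohort-to-residual variance
    # ratio as the DMI model
    cohort_scale = np.sqrt(config.cohort_r2 / config.rfi_variance_share)
    mfe_cohort = rng.normal(0.0, config.mfe_residual_sd * cohort_scale, n_trt)
    mpe_cohort = rng.normal(0.0, config.mpe_residual_sd * cohort_scale, n_trt)
    mfe_resid = (_residual("residual_MFE", config.mfe_residual_sd)
                 + mfe_cohort[treatment_of_cow])                 # g/kg DMI
    mpe_resid = (_residual("residual_MPE", config.mpe_residual_sd)
                 + mpe_cohort[treatment_of_cow])

    # --- DMI from the energy-sink model --------------------------------------
    b = config.dmi_coefficients
    var_fixed = _fixed_effect_variance(config)
    denom = 1.0 - config.cohort_r2 - config.rfi_variance_share
    total_var = var_fixed / denom
    sigma_cohort = np.sqrt(config.cohort_r2 * total_var)
    sigma_rfi = np.sqrt(config.rfi_variance_share * total_var)
    cohort_effects = rng.normal(0.0, sigma_cohort, n_trt)
    f_rfi = fracs.get("RFI", 0.0)
    rfi_noise = rng.standard_normal(n)

    # milk perturbations applied before DMI so the DMI equation holds exactly
    # against the final recorded NESec
    mean_dmi = means["DMI"]
    fat_kg = np.clip(fat_kg + mfe_resid * mean_dmi / 1000.0, 0.05, None)
    protein_kg = np.clip(protein_kg + mpe_resid * mean_dmi / 1000.0, 0.05, None)
    nesec = (NESEC_FAT * fat_kg + NESEC_PROTEIN * protein_kg
             + NESEC_LACTOSE * lactose_kg)

    # CLR closure gives the realized score accidental in-sample correlation
    # with the covariates and the other planted sets; residualize it against
    # the full design so the configured coefficients are the exact estimand
    basis = np.column_stack([
        np.ones(n), parity, mbw, bec, nesec,
        scores["residual_MFE"], scores["residual_MPE"],
        np.eye(n_trt)[treatment_of_cow][:, 1:],
    ])
    proj, *_ = np.linalg.lstsq(basis, scores["RFI"], rcond=None)
    scores["RFI"] = _standardize(scores["RFI"] - basis @ proj)
    rfi = sigma_rfi * (np.sqrt(f_rfi) * scores["RFI"]
                       + np.sqrt(1 - f_rfi) * rfi_noise)

    intercept = mean_dmi - (b["parity"] * config.multiparous_fraction
                            + b["MBW"] * means["MBW"]
                            + b["BEC"] * means["BEC"]
                            + b["NESec"] * means["NESec"])
    dmi = (intercept + b["parity"] * parity + b["MBW"] * mbw
           + b["BEC"] * bec + b["NESec"] * nesec
           + cohort_effects[treatment_of_cow] + rfi)
    dmi = np.clip(dmi, 5.0, None)

    # --- genomic PTA correlated with the cow's RFI-side signal ---------------
    rho = config.pta_correlation
    pta = rho * _standardize(rfi) + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)

    # --- per-experiment diet composition -------------------------------------
    diet_fa = np.clip(rng.normal(config.diet_fatty_acid_pct,
                                 config.diet_fatty_acid_sd, n_exp), 1.0, None)
    diet_ndf = np.clip(rng.normal(config.diet_ndf_pct,
                                  config.diet_ndf_sd, n_exp), 10.0, None)

    cows = pd.DataFrame({
        "cow_id": cow_ids,
        "parity": np.where(parity == 1, "multiparous", "primiparous"),
        "experiment_id": [exp_ids[e] for e in experiment_of_cow],
        "treatment_id": [trt_ids[t] for t in treatment_of_cow],
        "DMI": dmi,
        "BW": bw,
        "BCS": bcs,
        "BW_change": bw_change,
        "milk_kg": fat_kg + protein_kg + lactose_kg
        + milk_kg * (100 - fat_pct - protein_pct - lactose_pct) / 100.0,
        "fat_kg": fat_kg,
        "protein_kg": protein_kg,
        "lactose_kg": lactose_kg,
        "diet_fatty_acid_pct": diet_fa[experiment_of_cow],
        "diet_ndf_pct": diet_ndf[experiment_of_cow],
        "genomic_pta_rfi": pta,
    }).set_index("cow_id", drop=False)

    taxa = counts.taxon_ids
    truth = GroundTruth(
        planted_taxa={t: [taxa[i] for i in planted_idx[t]]
                      for t in PLANTABLE_TRAITS},
        effect_sizes=effect_sizes,
        planted_scores=scores,
        true_dmi_coefficients={"intercept": intercept, **b},
        true_cohort_effects=dict(zip(trt_ids, cohort_effects)),
        true_microbiome_variance_fraction=dict(fracs),
        true_rfi=rfi,
        true_pta=pta,
    )
    return cows, counts, truth
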