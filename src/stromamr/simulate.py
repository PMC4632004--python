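"""Synthetic bulk-expression cohorts with planted ground truth.

The generator emulates the statistical structure of a high-grade serous
ovarian carcinoma expression cohort: four latent molecular subtypes, a
stromal cell population admixed into every bulk sample at a per-sample
fraction ``f``, transcription-factor regulons with a controlled TF-target
correlation, and right-censored survival whose hazard depends on the
stroma-borne master-regulator programs.

Each bulk sample mixes the mean expression of two cell-population profiles,

    observed = baseline + (1 - f) * mean_epithelial + f * mean_stromal
               + deviations,

on log2 scale. Two regulator programs are over-expressed in the stromal
profile: a "mesenchymal" program (6 TFs by default, fibroblast-like) and an
"immunoreactive" program (10 TFs, immune-like), each TF with its target
regulon, scaled per sample by a lineage weight (fibroblast- vs immune-rich
stroma) and a per-regulon composition multiplier (cell-population
abundance). Bulk samples with more stroma therefore carry more signature
transcript — the mechanism by which stromal admixture drives two of the
four subtypes. Remaining TFs and their targets belong to the epithelial
(tumor-cell) profile, whose mean carries the subtype marker metagenes.

Sample-to-sample covariation is planted in the ``deviations`` term: the TF
deviation is i.i.d. standard normal and each target obeys

    target_dev = mode * a * dev(TF) + sqrt(1 - a^2) * noise,

with ``a = regulon_strength`` the TF-target Pearson correlation (exact in
expectation on observed data, since admixture shifts only profile means)
and ``mode`` +1 or -1.

Survival times are exponential with hazard
``lambda * exp(beta_mese * z_mese + beta_immu * z_immu)`` where the z's are
standardized per-sample signature means; censoring is an independent
exponential calibrated to the requested censoring rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSet, SurvivalTable

SUBTYPE_NAMES = ("differentiated", "mesenchymal", "immunoreactive",
                 "proliferative")

PAIRED_DESIGNS = ("stroma_vs_epithelium", "primary_vs_pdx",
                  "primary_vs_metastasis", "treated_vs_untreated")


class ConfigError(ValueError):
    """A cohort configuration violates its feasibility constraints."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults define the reference study conditions used throughout the test
    suite: a desk-scale cohort of 550 genes x 200 samples with 4 subtypes,
    16 stromal master-regulator TFs (6 mesenchymal + 10 immunoreactive) and
    4 epithelial TFs, 20 targets per TF at planted correlation 0.8.
    """

    n_genes: int = 550
    n_samples: int = 200
    n_subtypes: int = 4
    n_tfs: int = 20
    targets_per_tf: int = 20
    n_mese_tfs: int = 6
    n_immu_tfs: int = 10
    markers_per_subtype: int = 30
    regulon_strength: float = 0.8
    repressed_fraction: float = 0.2
    stromal_fraction_range: tuple[float, float] = (0.05, 0.65)
    noise_sd: float = 1.0
    marker_effect: float = 2.5
    stromal_shift: float = 2.0
    composition_sd: float = 0.4
    lineage_jitter_sd: float = 0.10
    baseline_hazard: float = 0.02          # events per month
    beta_mese: float = 0.7
    beta_immu: float = -0.5
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_subtypes < 3:
            raise ConfigError("n_subtypes must be >= 3 (subtype 1 is the "
                              "mesenchymal-like, subtype 2 the "
                              "immunoreactive-like cluster)")
        if self.n_mese_tfs + self.n_immu_tfs > self.n_tfs:
            raise ConfigError("n_mese_tfs + n_immu_tfs exceeds n_tfs")
        needed = (self.n_tfs * (1 + self.targets_per_tf)
                  + self.n_subtypes * self.markers_per_subtype)
        if needed > self.n_genes:
            raise ConfigError(
                f"gene budget infeasible: {needed} TF/target/marker genes "
                f"but only {self.n_genes} genes configured")
        lo, hi = self.stromal_fraction_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError("stromal_fraction_range must be ordered "
                              "within [0, 1]")
        if not (0.0 < self.regulon_strength < 1.0):
            raise ConfigError("regulon_strength must lie in (0, 1)")
        if not (0.0 <= self.repressed_fraction <= 1.0):
            raise ConfigError("repressed_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if self.beta_mese < 0 or self.beta_immu > 0:
            raise ConfigError("expected beta_mese >= 0 and beta_immu <= 0")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ConfigError("censor_rate must lie in [0, 1)")


@dataclass
class SyntheticCohort:
    """A generated cohort plus every piece of planted ground truth."""

    expression: ExpressionMatrix
    true_subtype: pd.Series                   # sample -> subtype name
    true_regulons: dict[str, dict[str, int]]  # tf -> {target: mode}
    stromal_fraction: pd.Series               # sample -> f in [0, 1]
    mese_signature: GeneSet
    immu_signature: GeneSet
    mese_mrs: GeneSet
    immu_mrs: GeneSet
    survival: SurvivalTable
    truth_betas: tuple[float, float]
    config: CohortConfig
    # pure cell-population profiles, kept for paired designs
    epithelial: np.ndarray = field(repr=False)
    stromal: np.ndarray = field(repr=False)

    @property
    def tf_list(self) -> list[str]:
        return sorted(self.true_regulons)

    @property
    def marker_truth(self) -> dict[str, set[str]]:
        """Planted subtype-specific marker genes, per subtype name."""
        out: dict[str, set[str]] = {}
        for g in self.expression.gene_ids:
            if ".mk" in g:
                out.setdefault(g.split(".")[0], set()).add(g)
        return out


BASELINE = 8.0          # log2 units added to every emitted value


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a cohort with planted subtypes, regulons and survival.

    Deterministic given ``config.seed``; all draws come from one seeded
    generator stream.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_genes, cfg.n_samples
    a = cfg.regulon_strength
    resid = math.sqrt(1.0 - a * a)

    # --- gene universe -----------------------------------------------------
    mese_tfs = [f"mTF{i + 1:02d}" for i in range(cfg.n_mese_tfs)]
    immu_tfs = [f"iTF{i + 1:02d}" for i in range(cfg.n_immu_tfs)]
    n_epi_tfs = cfg.n_tfs - cfg.n_mese_tfs - cfg.n_immu_tfs
    epi_tfs = [f"eTF{i + 1:02d}" for i in range(n_epi_tfs)]
    tfs = mese_tfs + immu_tfs + epi_tfs
    targets = {tf: [f"{tf}.t{j + 1:02d}" for j in range(cfg.targets_per_tf)]
               for tf in tfs}
    subtype_names = [SUBTYPE_NAMES[k] if k < len(SUBTYPE_NAMES)
                     else f"subtype{k + 1}" for k in range(cfg.n_subtypes)]
    markers = {name: [f"{name}.mk{j + 1:02d}"
                      for j in range(cfg.markers_per_subtype)]
               for name in subtype_names}
    structured = ([t for tf in tfs for t in [tf] + targets[tf]]
                  + [g for name in subtype_names for g in markers[name]])
    background = [f"bg{i + 1:04d}" for i in range(n - len(structured))]
    gene_ids = structured + background
    gidx = {g: i for i, g in enumerate(gene_ids)}
    sample_ids = [f"S{j + 1:03d}" for j in range(m)]

    # --- latent per-sample state ------------------------------------------
    labels = rng.integers(0, cfg.n_subtypes, size=m)
    lo, hi = cfg.stromal_fraction_range
    mid = 0.5 * (lo + hi)
    stroma_high = np.isin(labels, [1, 2])   # mesenchymal-, immunoreactive-like
    f = np.where(stroma_high, rng.uniform(mid, hi, size=m),
                 rng.uniform(lo, mid, size=m))
    # stromal lineage composition: fibroblast-rich for the mesenchymal-like
    # subtype, immune-rich for the immunoreactive-like, balanced otherwise;
    # per-sample jitter decouples the two programs so that discordant
    # (one-program-active) tumors exist in every subtype
    w_mese = np.where(labels == 1, 1.0, np.where(labels == 2, 0.6, 0.8))
    w_immu = np.where(labels == 2, 1.0, np.where(labels == 1, 0.6, 0.8))
    w_mese = np.clip(w_mese + rng.normal(0.0, cfg.lineage_jitter_sd, size=m),
                     0.1, None)
    w_immu = np.clip(w_immu + rng.normal(0.0, cfg.lineage_jitter_sd, size=m),
                     0.1, None)

    # --- mean structure of the two cell-population profiles ----------------
    # Admixture mixes the profile MEANS; regulon covariation enters at the
    # bulk level below, so the planted TF-target correlation equals
    # regulon_strength in the observed data regardless of f.
    mean_epi = np.zeros((n, m))
    mean_str = np.zeros((n, m))

    # subtype metagenes live in the epithelial (tumor-cell) profile
    for k, name in enumerate(subtype_names):
        rows = [gidx[g] for g in markers[name]]
        mean_epi[rows, :] += cfg.marker_effect * (labels == k)[None, :]

    # each stromal regulon is one cell population whose abundance varies
    # across tumors: a per-(regulon, sample) composition multiplier
    # modulates its over-expression
    sigma_v = math.sqrt(math.log(1.0 + cfg.composition_sd ** 2))
    true_regulons: dict[str, dict[str, int]] = {}
    n_rep = int(round(cfg.repressed_fraction * cfg.targets_per_tf))
    deviations = rng.normal(0.0, cfg.noise_sd, size=(n, m))
    for tf in tfs:
        stromal_tf = tf in mese_tfs or tf in immu_tfs
        if stromal_tf:
            lineage = w_mese if tf in mese_tfs else w_immu
            v = rng.lognormal(-0.5 * sigma_v ** 2, sigma_v, size=m)
            shift = cfg.stromal_shift * lineage * v
            rows = [gidx[tf]] + [gidx[t] for t in targets[tf]]
            mean_str[rows, :] += shift[None, :]
        dev = rng.normal(0.0, 1.0, size=m)
        deviations[gidx[tf]] = dev
        modes = np.ones(cfg.targets_per_tf, dtype=int)
        modes[:n_rep] = -1
        rng.shuffle(modes)
        true_regulons[tf] = {}
        for t, mode in zip(targets[tf], modes):
            deviations[gidx[t]] = (mode * a * dev
                                   + resid * rng.normal(0.0, 1.0, size=m))
            true_regulons[tf][t] = int(mode)

    observed = ((1.0 - f) * mean_epi + f * mean_str + deviations
                + BASELINE)
    epithelial = mean_epi + deviations + BASELINE
    stromal = mean_str + deviations + BASELINE

    # --- planted signatures ------------------------------------------------
    mese_sig_genes = frozenset(mese_tfs) | {t for tf in mese_tfs
                                            for t in targets[tf]}
    immu_sig_genes = frozenset(immu_tfs) | {t for tf in immu_tfs
                                            for t in targets[tf]}
    mese_signature = GeneSet("mesenchymal_signature",
                             "planted stroma-borne mesenchymal program",
                             frozenset(mese_sig_genes))
    immu_signature = GeneSet("immunoreactive_signature",
                             "planted stroma-borne immunoreactive program",
                             frozenset(immu_sig_genes))

    # --- survival ----------------------------------------------------------
    z_mese = _standardized_signature_mean(observed, gene_ids, mese_sig_genes)
    z_immu = _standardized_signature_mean(observed, gene_ids, immu_sig_genes)
    hazard = cfg.baseline_hazard * np.exp(cfg.beta_mese * z_mese
                                          + cfg.beta_immu * z_immu)
    event_time = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        lam_c = (cfg.censor_rate / (1.0 - cfg.censor_rate)) * hazard.mean()
        censor_time = rng.exponential(1.0 / lam_c, size=m)
    else:
        censor_time = np.full(m, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    survival = SurvivalTable(pd.DataFrame({
        "sample_id": sample_ids,
        "time": time,
        "event": event,
        "cohort_id": f"synthetic_seed{cfg.seed}",
    }))

    expression = ExpressionMatrix(gene_ids, sample_ids, observed,
                                  dataset_id=f"synthetic_seed{cfg.seed}")
    return SyntheticCohort(
        expression=expression,
        true_subtype=pd.Series([subtype_names[k] for k in labels],
                               index=sample_ids, name="subtype"),
        true_regulons=true_regulons,
        stromal_fraction=pd.Series(f, index=sample_ids, name="stromal_fraction"),
        mese_signature=mese_signature,
        immu_signature=immu_signature,
        mese_mrs=GeneSet("mesenchymal_mrs", "planted mesenchymal MR TFs",
                         frozenset(mese_tfs)),
        immu_mrs=GeneSet("immunoreactive_mrs", "planted immunoreactive MR TFs",
                         frozenset(immu_tfs)),
        survival=survival,
        truth_betas=(cfg.beta_mese, cfg.beta_immu),
        config=cfg,
        epithelial=epithelial,
        stromal=stromal,
    )


def _standardized_signature_mean(values: np.ndarray, gene_ids: list[str],
                                 members: frozenset[str]) -> np.ndarray:
    rows = [i for i, g in enumerate(gene_ids) if g in members]
    score = values[rows].mean(axis=0)
    return (score - score.mean()) / score.std()


def generate_paired_design(cohort: SyntheticCohort, design: str,
                           n_pairs: int, seed: int = 0,
                           delta: float = 0.15, pdx_fraction: float = 0.02,
                           ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Emit a paired two-condition expression matrix from a cohort.

    Designs
    -------
    stroma_vs_epithelium
        Pure stromal (f=1) vs pure epithelial (f=0) profile of each sampled
        tumor — microdissection of the two compartments.
    primary_vs_pdx
        The bulk sample at its native stromal fraction vs the same tumor
        engrafted in a mouse, where human stroma is lost (f ~ 0).
    primary_vs_metastasis, treated_vs_untreated
        Native f vs f shifted upward by ``delta`` — stromal involvement
        rises with metastasis and after chemotherapy.

    Returns the paired matrix and a pairing table with one row per pair
    (pair_id, sample_id, column ids of the two members).
    """
    if design not in PAIRED_DESIGNS:
        raise ValueError(f"unknown paired design {design!r}; "
                         f"choose one of {PAIRED_DESIGNS}")
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    if n_pairs > cohort.expression.n_samples:
        raise ValueError("n_pairs exceeds cohort size")
    rng = np.random.default_rng(seed)
    m = cohort.expression.n_samples
    picked = rng.choice(m, size=n_pairs, replace=False)
    f = cohort.stromal_fraction.to_numpy()

    cond_a, cond_b = design.split("_vs_")
    if design == "treated_vs_untreated":
        # condition a (treated) is the f-shifted member
        fa = np.clip(f[picked] + delta, 0.0, 0.95)
        fb = f[picked]
    elif design == "stroma_vs_epithelium":
        fa = np.ones(n_pairs)
        fb = np.zeros(n_pairs)
    elif design == "primary_vs_pdx":
        fa = f[picked]
        fb = np.full(n_pairs, pdx_fraction)
    else:  # primary_vs_metastasis
        fa = f[picked]
        fb = np.clip(f[picked] + delta, 0.0, 0.95)

    E = cohort.epithelial[:, picked]
    S = cohort.stromal[:, picked]
    noise_sd = 0.1 * cohort.config.noise_sd   # fresh assay noise per member
    va = (1 - fa) * E + fa * S + rng.normal(0, noise_sd, E.shape)
    vb = (1 - fb) * E + fb * S + rng.normal(0, noise_sd, E.shape)

    sample_ids = [cohort.expression.sample_ids[j] for j in picked]
    cols_a = [f"P{i + 1:02d}_{cond_a}" for i in range(n_pairs)]
    cols_b = [f"P{i + 1:02d}_{cond_b}" for i in range(n_pairs)]
    values = np.empty((cohort.expression.n_genes, 2 * n_pairs))
    values[:, 0::2] = va
    values[:, 1::2] = vb
    columns = [c for pair in zip(cols_a, cols_b) for c in pair]
    matrix = ExpressionMatrix(list(cohort.expression.gene_ids), columns,
                              values, dataset_id=design)
    pairing = pd.DataFrame({
        "pair_id": [f"P{i + 1:02d}" for i in range(n_pairs)],
        "sample_id": sample_ids,
        cond_a: cols_a,
        cond_b: cols_b,
    })
    return matrix, pairing
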