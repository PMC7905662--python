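"""Synthetic expression cohorts with planted glycolysis structure.

The generator emulates the statistical shape of a bulk RNA-Seq tumor cohort:
negative-binomial counts over log-normal library sizes, a latent per-sample
glycolytic activity that differs between planted patient clusters, a block of
"glycolysis" genes whose means track that activity, lncRNAs mixed with the
latent activity at a controlled Pearson correlation, exponential survival with
cluster-specific hazards, a mutation feature enriched in the high-activity
cluster, and copy-number/methylation covariates partially confounded with
lncRNA expression.  Every downstream stage therefore has a parameter-recovery
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (
    CODING,
    LNCRNA,
    ClinicalTable,
    CountMatrix,
    GeneSetCollection,
    RegulonCollection,
)

REFERENCE_LIBRARY = 1_000_000.0
GLYCOLYSIS_SET = "GLYCOLYSIS"
CHECKPOINT_SET = "CHECKPOINT"

# within-cluster standard deviation of the latent glycolytic activity; the
# cluster means sit at -1/0/+1 times cluster_shift, so shift=1 gives a
# ten-sigma separation between adjacent clusters: cluster identity, not
# within-cluster drift, carries the planted activity differences
LATENT_SD = 0.1
# log2-scale coupling of planted lncRNAs (and glycolysis genes) to the latent
LNC_COUPLING = 1.2
MEDIATOR_COUPLING = 2.5
GLY_COUPLING = 0.6
# share of a planted lncRNA's non-glycolytic variance that follows a
# cluster-specific pattern orthogonal to the activity gradient (subtypes have
# expression programs beyond the glycolysis axis); the remainder is
# independent noise
CLUSTER_PATTERN_SHARE = 0.5


class ConfigurationError(ValueError):
    """A cohort configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults describe the standard planted cohort used across the test
    suite: 150 samples in three clusters, 40 lncRNAs correlated with the
    latent glycolytic activity at |r| = 0.6, a three-fold hazard spread
    between extreme clusters, and an eight-fold mutation odds enrichment.
    """

    n_samples: int = 150
    n_coding_genes: int = 2000
    n_lncrnas: int = 120
    n_clusters: int = 3
    cluster_proportions: tuple[float, ...] | None = None
    glycolysis_set_size: int = 50
    n_pos_lnc: int = 20
    n_neg_lnc: int = 20
    target_correlation: float = 0.6
    mediator_correlation: float = 0.9
    cluster_shift: float = 1.0
    nb_dispersion: float = 0.3
    survival_hazard_ratios: tuple[float, ...] = (1.0, 1.5, 3.0)
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censoring_rate: float = 0.3
    n_mutation_features: int = 20
    mutation_background_rate: float = 0.15
    mutation_enrichment_odds: float = 8.0
    n_decoy_sets: int = 5
    n_immune_sets: int = 4
    immune_set_size: int = 10
    checkpoint_set_size: int = 8
    immune_shift: float = 0.8
    checkpoint_shift: float = 1.5
    n_assoc_coding: int = 50
    assoc_coupling: float = 1.5
    n_tfs: int = 30
    n_active_tfs: int = 3
    targets_per_tf: int = 10
    tf_effect: float = 1.2
    n_compartment_samples: int = 15
    nuclear_fraction: float = 0.7
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.cluster_proportions is None:
            return np.full(self.n_clusters, 1.0 / self.n_clusters)
        return np.asarray(self.cluster_proportions, dtype=float)

    def validate(self) -> None:
        for name in (
            "n_samples",
            "n_coding_genes",
            "n_lncrnas",
            "n_clusters",
            "glycolysis_set_size",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        props = self.proportions()
        if len(props) != self.n_clusters:
            raise ConfigurationError("cluster_proportions length != n_clusters")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError("cluster_proportions must sum to 1")
        if (props <= 0).any():
            raise ConfigurationError("cluster_proportions must be positive")
        if self.n_pos_lnc + self.n_neg_lnc > self.n_lncrnas:
            raise ConfigurationError("n_pos_lnc + n_neg_lnc exceeds n_lncrnas")
        if self.glycolysis_set_size > self.n_coding_genes:
            raise ConfigurationError("glycolysis_set_size exceeds n_coding_genes")
        if not 0.0 < self.target_correlation < 1.0:
            raise ConfigurationError("target_correlation must lie in (0, 1)")
        if self.cluster_shift < 0:
            raise ConfigurationError("cluster_shift must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if len(self.survival_hazard_ratios) != self.n_clusters:
            raise ConfigurationError("survival_hazard_ratios length != n_clusters")
        if any(h <= 0 for h in self.survival_hazard_ratios):
            raise ConfigurationError("hazard ratios must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigurationError("censoring_rate must lie in [0, 1)")
        if self.mutation_enrichment_odds < 1.0:
            raise ConfigurationError("mutation_enrichment_odds must be >= 1")
        if self.targets_per_tf < 5:
            raise ConfigurationError("targets_per_tf must be >= 5")
        needed = (
            self.glycolysis_set_size
            + self.n_assoc_coding
            + self.n_tfs * self.targets_per_tf
            + self.n_immune_sets * self.immune_set_size
            + self.checkpoint_set_size
        )
        if needed > self.n_coding_genes:
            raise ConfigurationError(
                f"coding universe too small: need {needed} genes for the "
                f"glycolysis/TF-target/immune/checkpoint blocks"
            )

    def null(self) -> "CohortConfig":
        """The no-structure counterpart: every planted effect neutralized."""
        return replace(
            self,
            cluster_shift=0.0,
            survival_hazard_ratios=tuple(1.0 for _ in range(self.n_clusters)),
            mutation_enrichment_odds=1.0,
            n_pos_lnc=0,
            n_neg_lnc=0,
            immune_shift=0.0,
            checkpoint_shift=0.0,
            tf_effect=0.0,
            assoc_coupling=0.0,
        )


@dataclass
class CohortTruth:
    """Ground truth planted into a cohort."""

    labels: pd.Series  # per-sample cluster in 1..K
    latent_activity: pd.Series  # latent glycolysis activity g
    planted_lncrnas: pd.DataFrame  # feature_id, sign, target_correlation, mediator
    enriched_mutation: str
    active_tfs: list[str]
    infiltrated: pd.Series  # binary, immune-marker upshift indicator


@dataclass
class CohortBundle:
    counts: CountMatrix
    clinical: ClinicalTable
    mutations: pd.DataFrame
    cnv: pd.DataFrame
    methylation: pd.DataFrame
    gene_sets: GeneSetCollection
    regulons: RegulonCollection
    truth: CohortTruth


# ---------------------------------------------------------------------------
# deterministic layout of the feature universe
# ---------------------------------------------------------------------------


def _coding_ids(config: CohortConfig) -> list[str]:
    return [f"PCG{i:04d}" for i in range(config.n_coding_genes)]


def _lnc_ids(config: CohortConfig) -> list[str]:
    return [f"LNC{i:04d}" for i in range(config.n_lncrnas)]


def _tf_ids(config: CohortConfig) -> list[str]:
    return [f"TF{i:03d}" for i in range(config.n_tfs)]


def _blocks(config: CohortConfig) -> dict[str, list[str]]:
    """Carve the coding universe into disjoint functional blocks.

    Layout is deterministic in the dimensions alone so that
    :func:`generate_gene_sets`, :func:`generate_regulons` and
    :func:`generate_cohort` agree without sharing state.
    """
    coding = _coding_ids(config)
    pos = 0

    def take(n: int) -> list[str]:
        nonlocal pos
        block = coding[pos : pos + n]
        pos += n
        return block

    blocks = {"glycolysis": take(config.glycolysis_set_size)}
    blocks["assoc"] = take(config.n_assoc_coding)
    for t in range(config.n_tfs):
        blocks[f"tf{t}"] = take(config.targets_per_tf)
    for i in range(config.n_immune_sets):
        blocks[f"immune{i}"] = take(config.immune_set_size)
    blocks["checkpoint"] = take(config.checkpoint_set_size)
    blocks["background"] = coding[pos:]
    return blocks


def generate_gene_sets(config: CohortConfig, seed_offset: int = 1) -> GeneSetCollection:
    """Gene sets for the cohort: the planted glycolysis set, size-matched
    uniform decoy sets, disjoint immune-cell marker blocks, and the
    immune-checkpoint list."""
    config.validate()
    rng = np.random.default_rng([config.seed, seed_offset])
    blocks = _blocks(config)
    coding = _coding_ids(config)
    sets: dict[str, set[str]] = {GLYCOLYSIS_SET: set(blocks["glycolysis"])}
    desc = {GLYCOLYSIS_SET: "planted glycolysis gene set"}
    for d in range(config.n_decoy_sets):
        members = rng.choice(coding, size=config.glycolysis_set_size, replace=False)
        sets[f"DECOY{d}"] = set(members)
        desc[f"DECOY{d}"] = "uniform decoy set of matched size"
    for i in range(config.n_immune_sets):
        sets[f"IMMUNE_CELL_{i}"] = set(blocks[f"immune{i}"])
        desc[f"IMMUNE_CELL_{i}"] = "immune-cell marker block"
    sets[CHECKPOINT_SET] = set(blocks["checkpoint"])
    desc[CHECKPOINT_SET] = "immune checkpoint gene list"
    return GeneSetCollection(sets, desc)


def generate_regulons(config: CohortConfig, seed_offset: int = 2) -> RegulonCollection:
    """TF regulons over disjoint coding-gene target blocks with random
    regulation modes; the first ``n_active_tfs`` are planted active in the
    high-activity cluster."""
    config.validate()
    rng = np.random.default_rng([config.seed, seed_offset])
    blocks = _blocks(config)
    regs: dict[str, list[tuple[str, int]]] = {}
    for t, tf in enumerate(_tf_ids(config)):
        targets = blocks[f"tf{t}"]
        modes = rng.choice([1, -1], size=len(targets))
        regs[tf] = [(g, int(m)) for g, m in zip(targets, modes)]
    return RegulonCollection(regs)


# ---------------------------------------------------------------------------
# count model
# ---------------------------------------------------------------------------


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _empirical_attenuation(
    rng: np.random.Generator,
    log2_base: float,
    coupling: float,
    dispersion: float,
    n_mc: int = 4000,
) -> float:
    """Monte-Carlo estimate of how NB count noise (plus the log pseudo-count)
    attenuates the correlation between a gene's observed log2 expression and
    its latent driver.

    Simulates log2 mean = base + coupling * z with z ~ N(0,1) under log-normal
    library-size variation and returns corr(log2(count + 1), z); the planted
    mixing weight is the target correlation divided by this factor.
    """
    z = rng.normal(0.0, 1.0, size=n_mc)
    lib_factor = np.exp(rng.normal(0.0, 0.25, size=n_mc))
    mu = np.exp2(log2_base + coupling * z) * lib_factor
    counts = _nb_counts(rng, mu, dispersion)
    obs = np.log2(counts / lib_factor + 1.0)
    return float(np.corrcoef(obs, z)[0, 1])


def _solve_censoring_horizon(hazards: np.ndarray, rate: float) -> float:
    """Administrative-censoring horizon u with C ~ U(0, u) matching the
    requested expected censoring fraction."""

    def expected_censoring(u: float) -> float:
        hu = hazards * u
        return float(np.mean((1.0 - np.exp(-hu)) / hu))

    lo, hi = 1e-6, 1e-6
    while expected_censoring(hi) > rate and hi < 1e12:
        hi *= 10.0
    return brentq(lambda u: expected_censoring(u) - rate, lo, hi)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Draw one cohort with planted structure; bit-identical for equal config."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_samples
    K = config.n_clusters
    sample_ids = [f"S{j:04d}" for j in range(n)]

    # --- cluster labels (largest-remainder allocation, then shuffled) ----
    props = config.proportions()
    counts_per = np.floor(props * n).astype(int)
    remainder = n - counts_per.sum()
    order = np.argsort(-(props * n - counts_per))
    counts_per[order[:remainder]] += 1
    labels = np.repeat(np.arange(1, K + 1), counts_per)
    labels = rng.permutation(labels)

    # --- latent glycolytic activity ------------------------------------
    if K > 1:
        centers = config.cluster_shift * (2.0 * (labels - 1) / (K - 1) - 1.0)
    else:
        centers = np.zeros(n)
    g = centers + rng.normal(0.0, LATENT_SD, size=n)
    g_sd = g.std(ddof=0)
    g_std = (g - g.mean()) / g_sd if g_sd > 0 else np.zeros(n)

    # cluster-pattern direction: quadratic contrast over cluster indices,
    # orthogonalized against the activity gradient so planted correlations
    # with g are unaffected
    if K >= 3 and config.cluster_shift > 0:
        quad = (labels - labels.mean()) ** 2
        q_pat = quad - quad.mean()
        if g_sd > 0:
            q_pat = q_pat - g_std * (q_pat @ g_std) / (g_std @ g_std)
        q_sd = q_pat.std(ddof=0)
        q_std = q_pat / q_sd if q_sd > 0 else np.zeros(n)
    else:
        q_std = np.zeros(n)

    blocks = _blocks(config)
    coding = _coding_ids(config)
    lnc = _lnc_ids(config)
    high = labels == K

    # --- per-gene base abundance on log2 expected counts at 1e6 library --
    # baselines are a property of the gene universe, not of the cohort:
    # independently seeded cohorts share them, as real cohorts share a genome
    rng_base = np.random.default_rng([config.n_coding_genes, config.n_lncrnas, 77])
    log2_base_coding = rng_base.normal(5.0, 1.5, size=config.n_coding_genes)
    # keep planted blocks well expressed so they survive the count filter
    idx = {g_: i for i, g_ in enumerate(coding)}
    for name in ("glycolysis", "assoc", "checkpoint", *[f"immune{i}" for i in range(config.n_immune_sets)]):
        for g_id in blocks[name]:
            log2_base_coding[idx[g_id]] = rng_base.normal(6.0, 0.8)
    for t in range(config.n_tfs):
        for g_id in blocks[f"tf{t}"]:
            log2_base_coding[idx[g_id]] = rng_base.normal(6.0, 0.8)

    log2_mu_coding = np.tile(log2_base_coding[:, None], (1, n)).astype(float)
    # glycolysis genes track the latent activity
    gly_rows = [idx[g_] for g_ in blocks["glycolysis"]]
    log2_mu_coding[gly_rows, :] += GLY_COUPLING * g
    # coding genes co-regulated with glycolytic activity (half up, half down):
    # the monotone expression programs the cluster classifier learns from
    assoc = blocks["assoc"]
    half = len(assoc) // 2
    for j, g_id in enumerate(assoc):
        direction = 1.0 if j < half or half == 0 else -1.0
        log2_mu_coding[idx[g_id], :] += direction * config.assoc_coupling * g

    # active-TF targets shift (by mode) in the highest cluster
    regulons = generate_regulons(config)
    active_tfs = _tf_ids(config)[: config.n_active_tfs]
    for tf in active_tfs:
        for target, mode in regulons[tf]:
            log2_mu_coding[idx[target], high] += mode * config.tf_effect

    # immune infiltration: the high cluster is preferentially infiltrated
    p_inf = np.where(high, 0.8, 0.2) if config.immune_shift > 0 else np.zeros(n)
    infiltrated = rng.random(n) < p_inf
    for i in range(config.n_immune_sets):
        for g_id in blocks[f"immune{i}"]:
            log2_mu_coding[idx[g_id], infiltrated] += config.immune_shift
    for g_id in blocks["checkpoint"]:
        log2_mu_coding[idx[g_id], high] += config.checkpoint_shift

    # --- lncRNAs: planted positive/negative correlates of g -------------
    n_planted = config.n_pos_lnc + config.n_neg_lnc
    signs = np.concatenate(
        [np.ones(config.n_pos_lnc), -np.ones(config.n_neg_lnc)]
    ).astype(int)
    log2_base_lnc = rng_base.normal(6.0, 0.5, size=config.n_lncrnas)
    # planted lncRNAs model the *expressed* glycolysis-correlated lncRNAs the
    # selection stage studies: abundant enough that the coupling's downswing
    # never pulls them under the expressed-gene count filter
    n_planted_total = config.n_pos_lnc + config.n_neg_lnc
    if n_planted_total:
        log2_base_lnc[:n_planted_total] = 8.0 + 0.3 * rng_base.normal(
            size=n_planted_total
        )
    log2_mu_lnc = np.tile(log2_base_lnc[:, None], (1, n)).astype(float)
    planted_rows = []
    latent_z = np.zeros((n_planted, n))
    for i in range(n_planted):
        mediator = i == 0 and signs[i] > 0
        coupling = MEDIATOR_COUPLING if mediator else LNC_COUPLING
        target = config.mediator_correlation if mediator else config.target_correlation
        if mediator:
            # abundant enough that the strong coupling never drives counts
            # below the expressed-gene filter in low-activity samples
            log2_base_lnc[i] = 9.0
        attenuation = _empirical_attenuation(
            rng, log2_base_lnc[i], coupling, config.nb_dispersion
        )
        rho = min(target / attenuation, 0.995)
        eps = rng.normal(0.0, 1.0, size=n)
        # orthogonalize the noise against g (and the cluster pattern) so
        # corr(z, g) is exactly rho
        for basis in (g_std, q_std):
            denom = basis @ basis
            if denom > 0:
                eps = eps - basis * (eps @ basis) / denom
        eps_sd = eps.std(ddof=0)
        eps = eps / eps_sd if eps_sd > 0 else eps
        kappa = rng.choice([1.0, -1.0])
        has_pattern = float(np.any(q_std != 0))
        a = np.sqrt(CLUSTER_PATTERN_SHARE * (1.0 - rho**2)) * has_pattern
        b = np.sqrt((1.0 - rho**2) - a**2)
        z = signs[i] * (rho * g_std + a * kappa * q_std + b * eps)
        latent_z[i] = z
        log2_mu_lnc[i, :] = log2_base_lnc[i] + coupling * z
        planted_rows.append(
            {
                "feature_id": lnc[i],
                "sign": int(signs[i]),
                "target_correlation": float(signs[i]) * target,
                "mediator": mediator,
            }
        )
    planted = pd.DataFrame(
        planted_rows, columns=["feature_id", "sign", "target_correlation", "mediator"]
    )

    # --- library sizes and counts ---------------------------------------
    lib = np.exp(rng.normal(np.log(REFERENCE_LIBRARY), 0.25, size=n))
    scale = lib / REFERENCE_LIBRARY
    mu = np.vstack([np.exp2(log2_mu_coding), np.exp2(log2_mu_lnc)]) * scale[None, :]
    counts = _nb_counts(rng, mu, config.nb_dispersion)
    feature_ids = coding + lnc
    feature_class = pd.Series(
        [CODING] * len(coding) + [LNCRNA] * len(lnc), index=feature_ids
    )
    count_matrix = CountMatrix(
        pd.DataFrame(counts, index=feature_ids, columns=sample_ids), feature_class
    )

    # --- survival --------------------------------------------------------
    hr = np.asarray(config.survival_hazard_ratios, dtype=float)
    hazards = config.baseline_hazard * hr[labels - 1]
    t_event = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        horizon = _solve_censoring_horizon(hazards, config.censoring_rate)
        t_cens = rng.uniform(0.0, horizon, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    clinical = ClinicalTable(
        pd.DataFrame(
            {"time": time, "event": event, "cluster_truth": labels},
            index=pd.Index(sample_ids, name="sample"),
        )
    )

    # --- mutations --------------------------------------------------------
    mut_ids = [f"MUT{i:03d}" for i in range(config.n_mutation_features)]
    p0 = config.mutation_background_rate
    odds_in = config.mutation_enrichment_odds * p0 / (1.0 - p0)
    p_in = odds_in / (1.0 + odds_in)
    p_mat = np.full((config.n_mutation_features, n), p0)
    p_mat[0, high] = p_in
    mutations = pd.DataFrame(
        (rng.random(p_mat.shape) < p_mat).astype(np.int8),
        index=mut_ids,
        columns=sample_ids,
    )

    # --- covariates confounded with planted lncRNA expression ------------
    cnv_rows, meth_rows, cov_ids = [], [], []
    for i in range(n_planted):
        z = latent_z[i]
        cnv_rows.append(0.5 * z + rng.normal(0.0, 0.8, size=n))
        meth_rows.append(np.clip(0.5 - 0.15 * z + rng.normal(0.0, 0.1, size=n), 0, 1))
        cov_ids.append(lnc[i])
    if not cov_ids:  # null configuration: keep covariates for plumbing tests
        for i in range(min(5, config.n_lncrnas)):
            cnv_rows.append(rng.normal(0.0, 0.8, size=n))
            meth_rows.append(np.clip(rng.normal(0.5, 0.1, size=n), 0, 1))
            cov_ids.append(lnc[i])
    cnv = pd.DataFrame(cnv_rows, index=cov_ids, columns=sample_ids)
    methylation = pd.DataFrame(meth_rows, index=cov_ids, columns=sample_ids)

    truth = CohortTruth(
        labels=pd.Series(labels, index=sample_ids, name="cluster"),
        latent_activity=pd.Series(g, index=sample_ids, name="glycolysis_activity"),
        planted_lncrnas=planted,
        enriched_mutation=mut_ids[0],
        active_tfs=active_tfs,
        infiltrated=pd.Series(infiltrated.astype(int), index=sample_ids),
    )
    return CohortBundle(
        counts=count_matrix,
        clinical=clinical,
        mutations=mutations,
        cnv=cnv,
        methylation=methylation,
        gene_sets=generate_gene_sets(config),
        regulons=regulons,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# compartment expression (cytoplasmic / nuclear)
# ---------------------------------------------------------------------------


def generate_compartment_expression(
    config: CohortConfig, seed_offset: int = 3
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Paired cytoplasmic/nuclear count matrices over the cohort's features.

    Coding genes are compartment-neutral ballast; a ``nuclear_fraction`` of
    lncRNAs receives a negative expected cytoplasm/nucleus log-ratio, the rest
    positive.  Returns (cytoplasmic, nuclear, truth) where truth carries the
    planted ``expected_log2_ratio`` per lncRNA.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, seed_offset])
    m = config.n_compartment_samples
    coding, lnc = _coding_ids(config), _lnc_ids(config)
    sample_ids = [f"CL{j:02d}" for j in range(m)]

    nuclear = rng.random(config.n_lncrnas) < config.nuclear_fraction
    magnitude = np.abs(rng.normal(2.0, 0.5, size=config.n_lncrnas))
    delta = np.where(nuclear, -magnitude, magnitude)

    base_coding = rng.normal(6.0, 1.0, size=config.n_coding_genes)
    base_lnc = rng.normal(6.0, 0.8, size=config.n_lncrnas)
    log2_cyt = np.concatenate([base_coding, base_lnc + delta / 2.0])
    log2_nuc = np.concatenate([base_coding, base_lnc - delta / 2.0])

    def draw(log2_mu: np.ndarray) -> np.ndarray:
        mu = np.exp2(log2_mu)[:, None] * np.ones((1, m))
        return _nb_counts(rng, mu, config.nb_dispersion)

    features = coding + lnc
    fc = pd.Series([CODING] * len(coding) + [LNCRNA] * len(lnc), index=features)
    cyt = CountMatrix(pd.DataFrame(draw(log2_cyt), index=features, columns=sample_ids), fc)
    nuc = CountMatrix(pd.DataFrame(draw(log2_nuc), index=features, columns=sample_ids), fc)
    truth = pd.DataFrame(
        {"expected_log2_ratio": delta, "nuclear": nuclear}, index=lnc
    )
    return cyt, nuc, truth
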