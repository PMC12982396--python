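"""Synthetic cohorts for the in vitro omalizumab-response assay.

This module generates the three data layers the analysis pipeline consumes,
with the statistical structure the downstream stages assume:

* event-level flow cytometry for the basophil activation test (BAT) under the
  four culture conditions (control, omalizumab, allergen, allergen+omalizumab),
  including allergen-induced CD63 up-regulation and the activation-associated
  scatter alteration that moves strongly activated basophils out of the
  standard scatter gate ("missing" basophils);
* a negative-binomial gene-by-sample count matrix in which RSAD2 (viperin)
  declines log-linearly with the BAT fold change while all other genes are
  null, plus a qPCR Ct layer with a triple housekeeping-gene reference; and
* a small longitudinal whole-blood expression table emulating patients
  followed over 0/3/6 months of omalizumab therapy.

Every donor carries a latent blockade strength ``rho`` in [0, 1] (1 = full
omalizumab blockade of allergen-induced activation); the pipeline's BAT fold
change is an estimator of the corresponding activity ratio, so generator truth
and pipeline output can be compared directly in tests.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq


class Condition(str, Enum):
    """The four culture conditions of one donor's assay."""

    CTRL = "CTRL"          # no treatment
    OMA = "OMA"            # omalizumab pre-treatment only
    ALG = "ALG"            # allergen challenge
    ALG_OMA = "ALG_OMA"    # omalizumab pre-treatment + allergen challenge


CONDITIONS: tuple[Condition, ...] = (
    Condition.CTRL, Condition.OMA, Condition.ALG, Condition.ALG_OMA
)

#: Channel columns of an event table, linear intensities.
CHANNELS: tuple[str, ...] = (
    "FSC_A", "FSC_H", "SSC_A", "CD45", "CD123", "HLA_DR", "CD63"
)

ALLERGENS = ("grass_pollen", "dust_mite")

# sub-stream tags for SeedSequence spawning
_TAG_COHORT = 101
_TAG_EXPR = 103
_TAG_CT = 104
_TAG_CLIN = 105


class ConfigurationError(ValueError):
    """Raised when a generator configuration field is out of range."""


def _require(ok: bool, name: str, msg: str) -> None:
    if not ok:
        raise ConfigurationError(f"{name}: {msg}")


# ---------------------------------------------------------------------------
# donor and cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DonorProfile:
    """Latent parameters of one donor.

    Parameters
    ----------
    donor_id
        Unique identifier within a cohort.
    allergen
        ``"grass_pollen"`` or ``"dust_mite"`` — the donor-specific allergen.
    rho
        Omalizumab blockade strength in [0, 1]; 1 means the allergen-induced
        activation increment is fully suppressed.
    basophil_freq
        Putative-basophil share of the CD45+ leukocyte pool.
    baseline_activation
        CD63++ fraction of basophils without allergen challenge.
    reactivity
        Allergen-induced activation ceiling (CD63++ fraction of intact
        basophils under the patient-specific allergen at full dose).
    reactivity_untreated, reactivity_omalizumab
        Per-arm realizations of ``reactivity`` (independent lognormal assay
        jitter per culture arm); default to ``reactivity``.
    """

    donor_id: str
    allergen: str
    rho: float
    basophil_freq: float
    baseline_activation: float
    reactivity: float
    reactivity_untreated: float | None = None
    reactivity_omalizumab: float | None = None
    age: int = 14
    sex: str = "F"
    gina_step: int = 2

    def __post_init__(self) -> None:
        if self.reactivity_untreated is None:
            object.__setattr__(self, "reactivity_untreated", self.reactivity)
        if self.reactivity_omalizumab is None:
            object.__setattr__(self, "reactivity_omalizumab", self.reactivity)
        _require(self.allergen in ALLERGENS, "allergen", f"must be one of {ALLERGENS}")
        _require(0.0 <= self.rho <= 1.0, "rho", "must lie in [0, 1]")
        _require(0.0 < self.basophil_freq < 1.0, "basophil_freq", "must lie in (0, 1)")
        _require(0.0 < self.baseline_activation < 1.0,
                 "baseline_activation", "must lie in (0, 1)")
        for name in ("reactivity", "reactivity_untreated", "reactivity_omalizumab"):
            v = getattr(self, name)
            _require(0.0 < v <= 1.0, name, "must lie in (0, 1]")
            _require(v > self.baseline_activation, name,
                     "must exceed baseline_activation")
        _require(1 <= self.gina_step <= 5, "gina_step", "must lie in 1..5")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings.

    The effect-size defaults are the assay's published operating point: a mean
    allergen-induced fold change of 7.89 in corrected basophil activity, and
    altered-scatter shares of 6.57% (unchallenged) rising to 14.73% of
    putative basophils after allergen challenge.

    ``events_per_sample`` defaults to 8e5: the activation-loss correction
    differences two basophil fractions of order 1% of CD45+ events, so the
    per-sample basophil loss (roughly 0.08 x basophil_freq of CD45+ events)
    is resolved with <~25% relative error only when several hundred thousand
    events are acquired — rare-event counting statistics, not instrument
    limits, set this floor (see the methods note for the error budget).
    """

    n_donors: int = 6
    events_per_sample: int = 800_000
    seed: int = 0
    activation_fc_mean: float = 7.89
    missing_fraction_control: float = 0.0657
    missing_fraction_allergen: float = 0.1473
    bat_fc_range: tuple[float, float] = (0.3, 1.5)
    basophil_freq_range: tuple[float, float] = (0.005, 0.02)
    baseline_activation_range: tuple[float, float] = (0.01, 0.05)
    reactivity_half_width: float = 0.06
    arm_cv: float = 0.0
    doublet_fraction: float = 0.03
    debris_fraction: float = 0.02

    def __post_init__(self) -> None:
        _require(self.n_donors >= 2, "n_donors", "must be >= 2")
        _require(self.events_per_sample >= 1000, "events_per_sample", "must be >= 1000")
        for name in ("missing_fraction_control", "missing_fraction_allergen",
                     "doublet_fraction", "debris_fraction"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, "must lie in [0, 1]")
        _require(self.missing_fraction_allergen >= self.missing_fraction_control,
                 "missing_fraction_allergen", "must be >= missing_fraction_control")
        lo, hi = self.bat_fc_range
        _require(0.0 < lo < hi, "bat_fc_range", "must satisfy 0 < lo < hi")
        for name in ("basophil_freq_range", "baseline_activation_range"):
            lo, hi = getattr(self, name)
            _require(0.0 < lo < hi < 1.0, name, "must satisfy 0 < lo < hi < 1")
        _require(self.activation_fc_mean > 1.0, "activation_fc_mean", "must be > 1")
        _require(self.arm_cv >= 0.0, "arm_cv", "must be >= 0")
        p_lo, p_hi = self.reactivity_range
        _require(p_lo > self.baseline_activation_range[1],
                 "activation_fc_mean",
                 "implied reactivity overlaps the baseline-activation range; "
                 "increase activation_fc_mean or narrow baseline_activation_range")
        _require(p_hi < 0.95, "activation_fc_mean", "implied reactivity exceeds 0.95")

    @property
    def mean_reactivity(self) -> float:
        """Reactivity mean implied by the target mean allergen fold change.

        The cohort-mean fold change is E[A_ALG] * E[1/a0] for independent
        reactivity and baseline activation a0, with the corrected activity
        A_ALG = ((1-ma)*p + (ma-mc)) / (1-mc); invert for E[p].
        """
        lo, hi = self.baseline_activation_range
        inv_mean = math.log(hi / lo) / (hi - lo)
        mc = self.missing_fraction_control
        ma = self.missing_fraction_allergen
        mean_activity = self.activation_fc_mean / inv_mean
        return (mean_activity * (1.0 - mc) - (ma - mc)) / (1.0 - ma)

    @property
    def reactivity_range(self) -> tuple[float, float]:
        m = self.mean_reactivity
        return (m - self.reactivity_half_width, m + self.reactivity_half_width)


@dataclass(frozen=True)
class ExpressionConfig:
    """Settings of the expression / qPCR layer.

    ``rsad2_slope`` is the log2-expression change of RSAD2 per unit BAT fold
    change (negative: low RSAD2 tracks poor in vitro blockade). Reference
    (housekeeping) genes get their own small dispersion — they are chosen in
    practice precisely because they are stable.
    """

    n_genes: int = 200
    target_genes: tuple[str, ...] = ("RSAD2", "HERC5", "APOBEC3B", "OAS3")
    reference_genes: tuple[str, ...] = ("B2M", "GAPDH", "RNA18SN5")
    rsad2_slope: float = -2.0
    rsad2_intercept: float = 9.0
    dispersion: float = 0.10
    ref_dispersion: float = 0.02
    library_size_mean: int = 50_000
    size_factor_sd: float = 0.15
    ct_intercept: float = 38.0
    ct_slope: float = 1.0
    ct_noise_sd: float = 0.10
    ct_censor: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.dispersion > 0, "dispersion", "must be > 0")
        _require(self.ref_dispersion > 0, "ref_dispersion", "must be > 0")
        _require(self.ct_noise_sd >= 0, "ct_noise_sd", "must be >= 0")
        _require(self.library_size_mean > 0, "library_size_mean", "must be > 0")
        _require(self.n_genes >= len(self.target_genes) + len(self.reference_genes),
                 "n_genes", "must cover target and reference genes")
        overlap = set(self.target_genes) & set(self.reference_genes)
        _require(not overlap, "target_genes", f"overlap with reference genes: {overlap}")

    @property
    def gene_universe(self) -> tuple[str, ...]:
        n_null = self.n_genes - len(self.target_genes) - len(self.reference_genes)
        nulls = tuple(f"NULL{i:04d}" for i in range(1, n_null + 1))
        return self.reference_genes + self.target_genes + nulls


# ---------------------------------------------------------------------------
# latent activity model (shared by the generator and the expectation helpers)
# ---------------------------------------------------------------------------

def _activity(p_act: float, miss_challenged: float, miss_reference: float) -> float:
    """Corrected activity implied by the generator's composition model.

    With the putative-basophil pool split ``1 - miss`` intact / ``miss``
    altered, the challenged-vs-reference basophil loss is ``miss_challenged -
    miss_reference`` (per unit pool), and the corrected readout
    (CD63++ + missing) / (total + missing) reduces to this closed form.
    """
    d = max(miss_challenged - miss_reference, 0.0)
    return ((1.0 - miss_challenged) * p_act + d) / ((1.0 - miss_challenged) + d)


def condition_parameters(
    donor: DonorProfile, condition: Condition | str, config: CohortConfig
) -> tuple[float, float]:
    """Return ``(activated_fraction, altered_scatter_share)`` for a condition.

    The activated fraction applies to intact basophils; the altered share is
    the fraction of the putative-basophil pool displaced out of the singlet
    scatter band. Under ALG_OMA both allergen-induced increments are scaled
    by ``1 - rho``.
    """
    condition = Condition(condition)
    a0 = donor.baseline_activation
    mc = config.missing_fraction_control
    ma = config.missing_fraction_allergen
    if condition in (Condition.CTRL, Condition.OMA):
        return a0, mc
    if condition is Condition.ALG:
        return donor.reactivity_untreated, ma
    u = 1.0 - donor.rho
    p = a0 + (donor.reactivity_omalizumab - a0) * u
    return p, mc + (ma - mc) * u


@dataclass(frozen=True)
class ResponseExpectation:
    """Noise-free activity quantities implied by a donor's latent parameters."""

    activity_reference: float      # c/b of the unchallenged control
    activity_allergen: float       # corrected activity, allergen arm
    activity_allergen_oma: float   # corrected activity, omalizumab arm
    fc_allergen: float
    bat_fc: float


def expected_response(donor: DonorProfile, config: CohortConfig) -> ResponseExpectation:
    """Expected pipeline readouts for a donor, before sampling noise."""
    mc = config.missing_fraction_control
    ma = config.missing_fraction_allergen
    p_alg, miss_alg = condition_parameters(donor, Condition.ALG, config)
    p_ao, miss_ao = condition_parameters(donor, Condition.ALG_OMA, config)
    a_alg = _activity(p_alg, miss_alg, mc)
    a_ao = _activity(p_ao, miss_ao, mc)
    a0 = donor.baseline_activation
    return ResponseExpectation(
        activity_reference=a0,
        activity_allergen=a_alg,
        activity_allergen_oma=a_ao,
        fc_allergen=a_alg / a0,
        bat_fc=a_ao / a_alg,
    )


def _invert_rho(target_bat_fc: float, donor_kwargs: dict, config: CohortConfig) -> float:
    """Blockade strength whose expected BAT fold change equals the target.

    Monotone in rho; targets outside the attainable range clip to 0 or 1.
    """
    def bat_fc_of(rho: float) -> float:
        d = DonorProfile(rho=rho, **donor_kwargs)
        return expected_response(d, config).bat_fc

    if target_bat_fc >= bat_fc_of(0.0):
        return 0.0
    if target_bat_fc <= bat_fc_of(1.0):
        return 1.0
    return float(brentq(lambda r: bat_fc_of(r) - target_bat_fc, 0.0, 1.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def sample_cohort(config: CohortConfig) -> list[DonorProfile]:
    """Draw a cohort of donor profiles.

    Deterministic given ``config.seed``. BAT-Fc targets are laid out as a
    jittered, shuffled linspace over ``bat_fc_range`` so that the cohort
    always spans both responder classes; each target is inverted to the
    latent blockade strength ``rho`` through the corrected-activity model.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _TAG_COHORT]))
    n = config.n_donors
    f_lo, f_hi = config.basophil_freq_range
    a_lo, a_hi = config.baseline_activation_range
    p_lo, p_hi = config.reactivity_range
    t_lo, t_hi = config.bat_fc_range

    freqs = rng.uniform(f_lo, f_hi, n)
    baselines = rng.uniform(a_lo, a_hi, n)
    reactivities = rng.uniform(p_lo, p_hi, n)
    step = (t_hi - t_lo) / max(n - 1, 1)
    targets = np.linspace(t_lo, t_hi, n) + rng.uniform(-0.5, 0.5, n) * step * 0.8
    targets = np.clip(targets, t_lo, t_hi)[rng.permutation(n)]
    arm_jitter = rng.normal(0.0, config.arm_cv, (n, 2))
    allergens = rng.choice(ALLERGENS, n)
    ages = rng.integers(6, 21, n)
    sexes = rng.choice(["M", "F"], n)
    gina = rng.integers(1, 5, n)

    donors: list[DonorProfile] = []
    for i in range(n):
        base = float(baselines[i])
        react = float(reactivities[i])
        lo_clip, hi_clip = base + 0.005, 0.98
        r_unt = float(np.clip(react * math.exp(arm_jitter[i, 0]), lo_clip, hi_clip))
        r_oma = float(np.clip(react * math.exp(arm_jitter[i, 1]), lo_clip, hi_clip))
        kwargs = dict(
            donor_id=f"D{i + 1:02d}",
            allergen=str(allergens[i]),
            basophil_freq=float(freqs[i]),
            baseline_activation=base,
            reactivity=react,
            reactivity_untreated=r_unt,
            reactivity_omalizumab=r_oma,
            age=int(ages[i]),
            sex=str(sexes[i]),
            gina_step=int(gina[i]),
        )
        rho = _invert_rho(float(targets[i]), kwargs, config)
        donors.append(DonorProfile(rho=rho, **kwargs))
    return donors


# ---------------------------------------------------------------------------
# event-level cytometry
# ---------------------------------------------------------------------------

#: Per-population lognormal channel models: (median, CV) on linear scale.
#: Marker separations are wide (>4 sigma from the default gate thresholds) so
#: gate placement, not spillover, determines recovery. No compensation is
#: modeled: the assay is a small panel and spillover is handled upstream.
CHANNEL_MODEL: dict[str, tuple[float, float]] = {
    "fsc_singlet": (100_000, 0.25),
    "fsc_baso": (90_000, 0.20),
    "fsc_altered": (70_000, 0.35),
    "fsc_doublet": (180_000, 0.30),
    "fsc_debris": (25_000, 0.35),
    "ratio_band": (1.0, 0.03),
    "ratio_offband": (0.55, 0.12),
    "ssc_leuk": (60_000, 0.50),
    "ssc_baso": (30_000, 0.30),
    "ssc_debris": (8_000, 0.50),
    "cd45_pos": (5_000, 0.30),
    "cd45_neg": (40, 0.50),
    "cd123_pos": (3_000, 0.30),
    "cd123_neg": (60, 0.50),
    "hladr_neg": (40, 0.40),
    "hladr_leuk": (400, 1.20),
    "cd63_pos": (4_000, 0.40),
    "cd63_neg": (80, 0.40),
}


def _lognormal(rng: np.random.Generator, key: str, n: int) -> np.ndarray:
    # float32 standard normals: event tables are large and channel dynamic
    # range is far below float32 limits
    median, cv = CHANNEL_MODEL[key]
    sigma = math.sqrt(math.log1p(cv * cv))
    x = rng.standard_normal(n, dtype=np.float32)
    x *= np.float32(sigma)
    x += np.float32(math.log(median))
    return np.exp(x, out=x)


def event_population_probabilities(
    donor: DonorProfile, condition: Condition | str, config: CohortConfig
) -> dict[str, float]:
    """Mixture weights of the six event populations for one sample."""
    p_act, miss = condition_parameters(donor, condition, config)
    f = donor.basophil_freq
    core = 1.0 - config.doublet_fraction - config.debris_fraction
    return {
        "debris": config.debris_fraction,
        "doublet": config.doublet_fraction,
        "leukocyte": core * (1.0 - f),
        "baso_intact_neg": core * f * (1.0 - miss) * (1.0 - p_act),
        "baso_intact_act": core * f * (1.0 - miss) * p_act,
        "baso_altered": core * f * miss,
    }


def expected_population_fractions(
    donor: DonorProfile, condition: Condition | str, config: CohortConfig
) -> dict[str, float]:
    """Noise-free gated fractions implied by the mixture weights.

    Keys: ``singlet_of_total``, ``cd45_of_singlets``, ``intact_of_cd45``,
    ``activated_of_intact``, ``altered_of_putative``.
    """
    p = event_population_probabilities(donor, condition, config)
    p_act, miss = condition_parameters(donor, condition, config)
    singlets = p["leukocyte"] + p["baso_intact_neg"] + p["baso_intact_act"] + p["debris"]
    cd45 = p["leukocyte"] + p["baso_intact_neg"] + p["baso_intact_act"]
    intact = p["baso_intact_neg"] + p["baso_intact_act"]
    return {
        "singlet_of_total": singlets,
        "cd45_of_singlets": cd45 / singlets,
        "intact_of_cd45": intact / cd45,
        "activated_of_intact": p_act,
        "altered_of_putative": miss,
    }


def sample_seed_sequence(
    seed: int, donor_id: str, condition: Condition | str
) -> np.random.SeedSequence:
    """Per-sample sub-stream from one global seed.

    Stable hashing of (donor_id, condition) keeps samples reproducible
    individually, without coupling across samples.
    """
    condition = Condition(condition)
    return np.random.SeedSequence([
        int(seed),
        zlib.crc32(donor_id.encode()),
        zlib.crc32(condition.value.encode()),
    ])


def simulate_events(
    donor: DonorProfile,
    condition: Condition | str,
    n_events: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Simulate one sample's event table.

    Six populations are mixed: CD45neg debris, doublets (FSC_H/FSC_A below
    the singlet band), non-basophil CD45+ leukocytes, intact basophils
    (CD63neg / CD63++), and altered-scatter basophils that retain the marker
    phenotype but sit outside the singlet band. Population weights come from
    :func:`event_population_probabilities`.
    """
    if n_events < 1:
        raise ConfigurationError("n_events: must be >= 1")
    condition = Condition(condition)
    config = config or CohortConfig()
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)

    probs = event_population_probabilities(donor, condition, config)
    names = list(probs)
    counts = rng.multinomial(n_events, np.asarray([probs[k] for k in names]))
    spec = {
        "debris": ("fsc_debris", "ratio_band", "ssc_debris",
                   "cd45_neg", "cd123_neg", "hladr_neg", "cd63_neg"),
        "doublet": ("fsc_doublet", "ratio_offband", "ssc_leuk",
                    "cd45_pos", "cd123_neg", "hladr_leuk", "cd63_neg"),
        "leukocyte": ("fsc_singlet", "ratio_band", "ssc_leuk",
                      "cd45_pos", "cd123_neg", "hladr_leuk", "cd63_neg"),
        "baso_intact_neg": ("fsc_baso", "ratio_band", "ssc_baso",
                            "cd45_pos", "cd123_pos", "hladr_neg", "cd63_neg"),
        "baso_intact_act": ("fsc_baso", "ratio_band", "ssc_baso",
                            "cd45_pos", "cd123_pos", "hladr_neg", "cd63_pos"),
        "baso_altered": ("fsc_altered", "ratio_offband", "ssc_baso",
                         "cd45_pos", "cd123_pos", "hladr_neg", "cd63_pos"),
    }
    n_total = int(counts.sum())
    data = np.empty((len(CHANNELS), n_total), dtype=np.float32)
    start = 0
    for name, k in zip(names, counts):
        k = int(k)
        if k == 0:
            continue
        sl = slice(start, start + k)
        keys = spec[name]  # fsc, ratio, ssc, cd45, cd123, hladr, cd63
        fsc_a = _lognormal(rng, keys[0], k)
        data[0, sl] = fsc_a
        data[1, sl] = fsc_a * _lognormal(rng, keys[1], k)
        for row, key in enumerate(keys[2:], start=2):
            data[row, sl] = _lognormal(rng, key, k)
        start += k
    data = data[:, rng.permutation(n_total)]
    events = pd.DataFrame(data.T, columns=list(CHANNELS), copy=False)
    codes = np.zeros(n_total, dtype=np.int8)
    events.insert(0, "donor_id",
                  pd.Categorical.from_codes(codes, categories=[donor.donor_id]))
    events.insert(1, "condition",
                  pd.Categorical.from_codes(codes, categories=[condition.value]))
    return events


def simulate_cohort_events(
    donors: Sequence[DonorProfile], config: CohortConfig
) -> Iterable[tuple[DonorProfile, Condition, pd.DataFrame]]:
    """Yield event tables for every donor x condition of a cohort."""
    for donor in donors:
        for condition in CONDITIONS:
            ss = sample_seed_sequence(config.seed, donor.donor_id, condition)
            yield donor, condition, simulate_events(
                donor, condition, config.events_per_sample, ss, config
            )


# ---------------------------------------------------------------------------
# expression layers
# ---------------------------------------------------------------------------

_REF_LOG2_BASE = {"B2M": 12.0, "GAPDH": 11.5, "RNA18SN5": 13.5}
_TARGET_LOG2_BASE = {"HERC5": 8.5, "APOBEC3B": 7.5, "OAS3": 8.0}


def simulate_expression(
    donors: Sequence[DonorProfile],
    true_bat_fc: Sequence[float],
    config: ExpressionConfig,
) -> pd.DataFrame:
    """Gene-by-sample negative-binomial count matrix.

    RSAD2's log2 mean is ``rsad2_intercept + rsad2_slope * bat_fc``; all
    other genes (including the remaining targets) are independent of the
    response. Per-sample lognormal size factors emulate library-depth
    variation; reference genes use ``ref_dispersion``.
    """
    donors = list(donors)
    fc = np.asarray(true_bat_fc, dtype=float)
    if len(donors) != fc.size:
        raise ValueError(
            f"length mismatch: {len(donors)} donors vs {fc.size} BAT Fc values"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _TAG_EXPR]))
    genes = config.gene_universe
    missing = set(config.target_genes) - set(genes)
    if missing:
        raise ConfigurationError(f"target_genes: not in gene universe: {missing}")
    n_s = len(donors)

    log2_means = np.empty((len(genes), n_s))
    dispersions = np.empty(len(genes))
    for gi, g in enumerate(genes):
        if g in config.reference_genes:
            base = _REF_LOG2_BASE.get(g, 12.0)
            log2_means[gi] = base
            dispersions[gi] = config.ref_dispersion
        elif g == "RSAD2":
            log2_means[gi] = config.rsad2_intercept + config.rsad2_slope * fc
            dispersions[gi] = config.dispersion
        elif g in config.target_genes:
            log2_means[gi] = _TARGET_LOG2_BASE.get(g, 8.0)
            dispersions[gi] = config.dispersion
        else:
            log2_means[gi] = rng.uniform(5.0, 9.0)
            dispersions[gi] = config.dispersion

    mu = 2.0 ** log2_means
    lib_scale = config.library_size_mean / mu.sum(axis=0).mean()
    size_factors = rng.lognormal(0.0, config.size_factor_sd, n_s)
    mu = mu * lib_scale * size_factors[None, :]

    n_param = 1.0 / dispersions[:, None]
    counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    return pd.DataFrame(counts, index=list(genes),
                        columns=[d.donor_id for d in donors])


def simulate_ct(counts: pd.DataFrame, config: ExpressionConfig) -> pd.DataFrame:
    """qPCR Ct table for a count-matrix subset (targets + reference genes).

    ``Ct = ct_intercept - ct_slope * log2(count) + N(0, ct_noise_sd)``; counts
    of zero and Ct values above ``ct_censor`` are emitted as censored wells
    (``ct`` NaN, ``censored`` True). Long format: sample_id, gene, ct,
    censored.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _TAG_CT]))
    rows = []
    values = counts.to_numpy(dtype=float)
    noise = rng.normal(0.0, config.ct_noise_sd, values.shape)
    for gi, gene in enumerate(counts.index):
        for si, sample in enumerate(counts.columns):
            x = values[gi, si]
            if x <= 0:
                rows.append((sample, gene, np.nan, True))
                continue
            ct = config.ct_intercept - config.ct_slope * math.log2(x) + noise[gi, si]
            if ct > config.ct_censor:
                rows.append((sample, gene, np.nan, True))
            else:
                rows.append((sample, gene, ct, False))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "ct", "censored"])


def simulate_clinical(
    n_responders: int,
    n_nonresponders: int,
    timepoints: Sequence[int] = (0, 3, 6),
    seed: int = 0,
    baseline_responder: float = 1.0,
    baseline_gap: float = 0.7,
    rise: float = 1.0,
    recovery: float = 0.8,
    noise_sd: float = 0.4,
) -> pd.DataFrame:
    """Longitudinal whole-blood RSAD2 expression over omalizumab therapy.

    Both groups rise from baseline to 3 months; responders fall back toward
    baseline by 6 months while non-responders stay elevated, and responders
    start from a higher baseline (``baseline_gap``). Values are linear
    relative expression, lognormal around the group trajectory.
    """
    if tuple(timepoints) != (0, 3, 6):
        raise ConfigurationError("timepoints: this generator models months (0, 3, 6)")
    if n_responders < 1 or n_nonresponders < 1:
        raise ConfigurationError("n_responders/n_nonresponders: must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_CLIN]))
    b = baseline_responder
    traj = {
        "responder": {0: b, 3: b + rise, 6: b + rise - recovery},
        "non_responder": {0: b - baseline_gap, 3: b - baseline_gap + rise,
                          6: b - baseline_gap + rise},
    }
    rows = []
    for group, count in (("responder", n_responders),
                         ("non_responder", n_nonresponders)):
        prefix = "R" if group == "responder" else "N"
        for i in range(count):
            subject = f"{prefix}{i + 1:02d}"
            for t in timepoints:
                mu = traj[group][t] + rng.normal(0.0, noise_sd)
                rows.append((subject, group, int(t), float(2.0 ** mu)))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "timepoint", "rsad2_rel_expr"]
    )
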