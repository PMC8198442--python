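"""Synthetic dose-time and microarray data with the study's measured structure.

The generator emulates a prednisolone dose-response experiment on a
glucocorticoid-resistant T-lymphoblastic leukemia culture:

* exponential growth calibrated to a 45.2 h control doubling time, with a
  mild mitogenic boost at nanomolar-micromolar doses;
* a biphasic death response — necrosis peaking at the 1.09 uM dose level
  at 72 h, apoptosis rising dose-dependently above ~10 uM and only late;
* forward-scatter cell size that swells transiently and shrinks by 72 h;
* supernatant biochemistry stoichiometrically coupled to growth: glucose
  consumption proportional to integrated population (suppressed at high
  dose), lactate produced at 2 mol per mol glucose scaled by a true
  efficiency alpha_true, LDH/ALP released by necrotic cells, and K+ affine
  in total population;
* triplicate two-channel microarrays in the simple-loop design
  (0v1, 1v3, 0v3) plus single reference designs '4' and '5', whose true
  log2 ratios satisfy the loop identity r(0v3) = r(0v1) + r(1v3) exactly
  and whose differential probes fall into four expression archetypes.

All randomness flows from a single seed; identical seeds give identical
datasets.  Measurement noise is multiplicative log-normal throughout
(positive-valued measurements).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import METABOLITE_UNITS, DoseTimeSeries, MetabolitePanel
from .microarray import LOOP_DESIGNS, REFERENCE_DESIGNS, TwoChannelArray

__all__ = [
    "StudyDesign",
    "GrowthTruth",
    "MetabolicTruth",
    "ArrayTruth",
    "generate_dataset",
    "generate_microarray_set",
]

DEFAULT_TIMES = (-24.0, 0.0, 4.0, 24.0, 48.0, 72.0)
DEFAULT_DOSES = (0.0, 0.01, 1.09, 10.0, 50.0, 100.0, 175.0, 700.0)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling grid of the experiment: times (h), doses (uM), seed."""

    times: tuple[float, ...] = DEFAULT_TIMES
    doses: tuple[float, ...] = DEFAULT_DOSES
    replicates_per_condition: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing (>= 2 points)")
        d = np.asarray(self.doses, dtype=float)
        if len(d) < 1 or (d < 0).any() or not np.all(np.diff(d) > 0):
            raise ValueError("doses must be non-negative and strictly increasing")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")


def _lognormal_bump(dose: np.ndarray, center: float, width: float) -> np.ndarray:
    """Bump in log-dose space, 0 at dose 0 (no drug, no effect)."""
    out = np.zeros_like(dose, dtype=float)
    pos = dose > 0
    out[pos] = np.exp(-((np.log(dose[pos] / center)) ** 2) / (2.0 * width**2))
    return out


@dataclass(frozen=True)
class GrowthTruth:
    """Ground truth for population growth, death fractions and cell size.

    ``control_doubling_time`` is the effective doubling time of the
    untreated culture over the whole 0-72 h window (hours).  The biphasic
    death response is encoded as a log-normal necrosis bump centred at
    ``necrosis_peak_dose`` and a saturating apoptosis curve with midpoint
    ``apoptosis_half_dose`` that only ramps up late (72 h).  ``noise_cv``
    is the coefficient of variation of the multiplicative log-normal
    measurement noise on counts, fractions and sizes.
    """

    control_doubling_time: float = 45.2
    seeding_density: float = 1100.0  # cells/uL at -24 h
    mitogenic_amp: float = 0.15
    mitogenic_center: float = 0.1  # uM
    mitogenic_width: float = 1.5  # ln-dose units
    necrosis_peak_dose: float = 1.09  # uM
    necrosis_width: float = 0.8  # ln-dose units
    necrosis_amp: float = 0.25
    necrosis_base: float = 0.03
    apoptosis_onset_dose: float = 10.0  # uM; response is small below this
    apoptosis_half_dose: float = 50.0  # uM
    apoptosis_amp: float = 0.40
    apoptosis_base: float = 0.04
    fs_baseline: float = 520.0  # forward scatter, a.u.
    noise_cv: float = 0.05

    # time-weight profile of the growth rate on the post-dose intervals
    # [0,4], [4,24], [24,48], [48,72]; time-weighted mean is exactly 1 so the
    # 0->72 h effective rate equals ln2/control_doubling_time.
    rate_time_weights: tuple[float, ...] = (1.0, 1.3, 1.0, 0.75)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.control_doubling_time <= 0:
            raise ValueError("control_doubling_time must be positive")

    def dose_modifier(self, dose: np.ndarray) -> np.ndarray:
        """Multiplicative growth-rate factor per dose (biphasic, > 0)."""
        dose = np.asarray(dose, dtype=float)
        return 1.0 + self.mitogenic_amp * _lognormal_bump(
            dose, self.mitogenic_center, self.mitogenic_width
        )

    def _time_weight(self, t0: float, t1: float) -> float:
        """Mean rate weight over [t0, t1] from the interval profile."""
        knots = [0.0, 4.0, 24.0, 48.0, 72.0]
        if t1 <= 0:
            return 1.0  # pre-dosing growth at the control profile
        total, span = 0.0, 0.0
        for k0, k1, w in zip(knots[:-1], knots[1:], self.rate_time_weights):
            lo, hi = max(t0, k0), min(t1, k1)
            if hi > lo:
                total += w * (hi - lo)
                span += hi - lo
        # outside the profiled window fall back to weight 1
        if span < (t1 - max(t0, 0.0)) - 1e-12:
            rest = (t1 - max(t0, 0.0)) - span
            total += rest
            span += rest
        return total / span if span > 0 else 1.0

    def population(self, doses: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Noiseless total population (cells/uL) on the grid."""
        mu0 = np.log(2.0) / self.control_doubling_time
        mod = self.dose_modifier(doses)
        n = np.empty((len(doses), len(times)))
        t0 = times[0]
        log_n = np.full(len(doses), np.log(self.seeding_density))
        # integrate piecewise-exponential growth from the first time point
        prev = t0
        for j, t in enumerate(times):
            if j > 0:
                seg_lo, seg_hi = prev, t
                # pre-dose part grows at the control rate for every flask
                pre_hi = min(seg_hi, 0.0)
                if pre_hi > seg_lo:
                    log_n = log_n + mu0 * (pre_hi - seg_lo)
                post_lo = max(seg_lo, 0.0)
                if seg_hi > post_lo:
                    w = self._time_weight(post_lo, seg_hi)
                    log_n = log_n + mu0 * mod * w * (seg_hi - post_lo)
                prev = t
            n[:, j] = np.exp(log_n)
        return n

    def _necrosis_ramp(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, [-24.0, 0.0, 4.0, 24.0, 48.0, 72.0], [0.0, 0.1, 0.15, 0.3, 0.6, 1.0])

    def _apoptosis_ramp(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, [-24.0, 0.0, 4.0, 24.0, 48.0, 72.0], [0.1, 0.1, 0.15, 0.25, 0.5, 1.0])

    def fractions(self, doses: np.ndarray, times: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Noiseless (viable, apoptotic, necrotic) fractions on the grid."""
        d = np.asarray(doses, dtype=float)[:, None]
        t = np.asarray(times, dtype=float)[None, :]
        nec = self.necrosis_base + self.necrosis_amp * _lognormal_bump(
            d.ravel(), self.necrosis_peak_dose, self.necrosis_width
        )[:, None] * self._necrosis_ramp(t.ravel())[None, :]
        hill = d / (d + self.apoptosis_half_dose)
        anti = 0.5 * _lognormal_bump(d.ravel(), self.mitogenic_center, self.mitogenic_width)[:, None]
        apo = (self.apoptosis_base * (1.0 - anti) + self.apoptosis_amp * hill) * (
            self._apoptosis_ramp(t.ravel())[None, :]
        )
        via = 1.0 - nec - apo
        if (via < 0).any():
            raise ValueError("death fractions exceed 1; truth parameters inconsistent")
        return via, apo, nec

    def fs_size(self, times: np.ndarray) -> np.ndarray:
        """Noiseless forward-scatter size (dose-independent trajectory)."""
        profile = np.interp(
            times, [-24.0, 0.0, 4.0, 24.0, 48.0, 72.0], [1.0, 1.0, 1.02, 1.015, 0.97, 0.90]
        )
        return self.fs_baseline * profile


@dataclass(frozen=True)
class MetabolicTruth:
    """Ground truth coupling supernatant biochemistry to the culture.

    ``alpha_true`` is the fraction of consumed glucose converted to lactate
    at the 2:1 molar stoichiometry of anaerobic glycolysis; with
    ``alpha_true = 1`` and zero noise the molar lactate rise is exactly
    twice the molar glucose fall.  ``uptake_suppression_half_dose`` sets
    where high prednisolone doses start suppressing glucose uptake.
    """

    alpha_true: float = 0.9
    baseline_glucose: float = 180.0  # mg/dL
    baseline_lactate: float = 10.0  # mg/dL
    glucose_uptake_rate: float = 4.5e-4  # mg/dL per (cell h / uL)
    uptake_suppression_half_dose: float = 20.0  # uM
    uptake_suppression_floor: float = 0.25
    ldh_baseline: float = 150.0  # IU/L
    ldh_release_per_necrotic_cell: float = 0.3  # IU/L per (cell/uL)
    alp_baseline: float = 40.0  # IU/L
    alp_scale: float = 0.05  # IU/L per (cell/uL) necrotic
    ion_baselines: dict = field(
        default_factory=lambda: {"k": 3.8, "na": 140.0, "ca": 2.2, "mg": 0.85}
    )
    k_per_cell: float = 4.0e-4  # mmol/L per (cell/uL)
    noise_cv: float = 0.03

    def __post_init__(self) -> None:
        if not (0 < self.alpha_true <= 1):
            raise ValueError("alpha_true must lie in (0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def uptake_suppression(self, dose: np.ndarray) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        return self.uptake_suppression_floor + (1.0 - self.uptake_suppression_floor) / (
            1.0 + d / self.uptake_suppression_half_dose
        )


def _ln_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative log-normal noise with unit median and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size=shape))


def generate_dataset(
    design: StudyDesign | None = None,
    growth: GrowthTruth | None = None,
    metab: MetabolicTruth | None = None,
) -> tuple[dict[str, DoseTimeSeries], MetabolitePanel]:
    """Generate the full dose-time dataset.

    Returns
    -------
    series : dict
        ``population`` (cells/uL), ``viable_fraction`` / ``apoptotic_fraction``
        / ``necrotic_fraction`` (dimensionless, summing to 1 per condition)
        and ``fs`` (forward scatter, a.u.), each a :class:`DoseTimeSeries`.
    panel : MetabolitePanel
        glucose/lactate (mg/dL), LDH/ALP (IU/L), K+/Na+/Ca2+/Mg2+ (mmol/L).
    """
    design = design or StudyDesign()
    growth = growth or GrowthTruth()
    metab = metab or MetabolicTruth()
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xD05E]))
    doses = np.asarray(design.doses, dtype=float)
    times = np.asarray(design.times, dtype=float)

    n_true = growth.population(doses, times)
    n_obs = n_true * _ln_noise(rng, growth.noise_cv, n_true.shape)

    via, apo, nec = growth.fractions(doses, times)
    frac = np.stack([via, apo, nec])
    frac = frac * _ln_noise(rng, growth.noise_cv, frac.shape)
    frac = frac / frac.sum(axis=0, keepdims=True)

    fs_true = np.broadcast_to(growth.fs_size(times), n_true.shape)
    fs_obs = fs_true * _ln_noise(rng, growth.noise_cv, fs_true.shape)

    def _series(name, unit, values):
        df = pd.DataFrame(values, index=doses, columns=times)
        return DoseTimeSeries(name, unit, df)

    series = {
        "population": _series("population", "cells/uL", n_obs),
        "viable_fraction": _series("viable_fraction", "", frac[0]),
        "apoptotic_fraction": _series("apoptotic_fraction", "", frac[1]),
        "necrotic_fraction": _series("necrotic_fraction", "", frac[2]),
        "fs": _series("fs", "a.u.", fs_obs),
    }

    # --- metabolites, coupled to the noiseless growth truth -----------------
    mu0 = np.log(2.0) / growth.control_doubling_time
    mod = growth.dose_modifier(doses)
    # integrated population (cell h / uL) from the first sampled time
    integral = np.zeros_like(n_true)
    for j in range(1, len(times)):
        # trapezoid on the sampled grid is exact enough for coupling purposes;
        # use analytic piecewise-exponential integral for fidelity
        t0, t1 = times[j - 1], times[j]
        n0, n1 = n_true[:, j - 1], n_true[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            local_mu = np.where(n1 != n0, np.log(n1 / n0) / (t1 - t0), mu0 * mod)
            seg = np.where(np.abs(local_mu) > 1e-12, (n1 - n0) / local_mu, n0 * (t1 - t0))
        integral[:, j] = integral[:, j - 1] + seg

    supp = metab.uptake_suppression(doses)[:, None]
    glc_consumed = metab.glucose_uptake_rate * supp * integral  # mg/dL
    glc_true = np.maximum(metab.baseline_glucose - glc_consumed, 0.0)
    glc_consumed = metab.baseline_glucose - glc_true
    # mass balance: MW(lactate) = MW(glucose)/2, so at alpha=1 the produced
    # lactate mass concentration equals the consumed glucose mass concentration
    lac_true = metab.baseline_lactate + metab.alpha_true * glc_consumed

    nec_count = n_true * nec
    ldh_true = metab.ldh_baseline + metab.ldh_release_per_necrotic_cell * nec_count
    alp_true = metab.alp_baseline + metab.alp_scale * nec_count
    k_true = metab.ion_baselines["k"] + metab.k_per_cell * n_true
    na_true = metab.ion_baselines["na"] * (1.0 + 0.01 * (k_true - k_true[:, :1]) / k_true[:, :1])
    ca_true = metab.ion_baselines["ca"] * (1.0 + 0.002 * (alp_true - metab.alp_baseline) / metab.alp_baseline)
    mg_true = np.full_like(n_true, metab.ion_baselines["mg"])

    analytes = {}
    for name, truth in [
        ("glucose", glc_true),
        ("lactate", lac_true),
        ("ldh", ldh_true),
        ("alp", alp_true),
        ("k", k_true),
        ("na", na_true),
        ("ca", ca_true),
        ("mg", mg_true),
    ]:
        obs = truth * _ln_noise(rng, metab.noise_cv, truth.shape)
        analytes[name] = _series(name, METABOLITE_UNITS[name], obs)

    return series, MetabolitePanel(analytes)


# ---------------------------------------------------------------------------
# Two-channel microarray generation
# ---------------------------------------------------------------------------

ARCHETYPE_PROFILES = {
    # (r_0v1, r_1v3, r_4, r_5): four biphasic expression archetypes; the
    # loop contrast r_0v3 is always r_0v1 + r_1v3 (exact additivity).
    1: (2.0, -3.0, -1.5, -2.0),  # up at low dose, down at high
    2: (-2.0, 3.0, 1.5, 2.0),  # down at low dose, up at high
    3: (1.5, 1.0, 1.0, 2.5),  # up throughout
    4: (-1.5, -1.0, -1.0, -2.5),  # down throughout
}


@dataclass(frozen=True)
class ArrayTruth:
    """Ground truth for the two-channel microarray set.

    ``n_probes`` spots per array; a fraction ``de_fraction`` of probes is
    differentially expressed, split evenly over ``n_clusters`` archetypes
    whose contrast profiles mirror the biphasic dose response.  Intensities
    follow foreground = local background x 2^(log2 signal), with
    ``spot_noise_sd`` the log2-scale SD of the multiplicative spot noise
    (applied to both the signal and the local background).
    """

    n_probes: int = 1200
    de_fraction: float = 0.10
    n_clusters: int = 4
    archetype_jitter_sd: float = 0.3  # log2; per-probe deviation from archetype
    base_log2_mean: float = 10.0
    base_log2_sd: float = 1.5
    background_level: float = 64.0
    spot_noise_sd: float = 0.15  # log2

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must lie in [0, 1]")
        if not (1 <= self.n_clusters <= len(ARCHETYPE_PROFILES)):
            raise ValueError(f"n_clusters must lie in 1..{len(ARCHETYPE_PROFILES)}")
        if self.spot_noise_sd < 0:
            raise ValueError("spot_noise_sd must be >= 0")

    def true_ratios(self, seed: int) -> pd.DataFrame:
        """Per-probe true log2 ratios for every design label.

        Loop additivity holds exactly: ratio(0v3) = ratio(0v1) + ratio(1v3).
        """
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA88A]))
        n_de = int(round(self.de_fraction * self.n_probes))
        probes = [f"P{i:05d}" for i in range(self.n_probes)]
        r = pd.DataFrame(
            0.0, index=probes, columns=["0v1", "1v3", "0v3", "4", "5"]
        )
        archetypes = np.zeros(self.n_probes, dtype=int)
        if n_de:
            labels = np.arange(n_de) % self.n_clusters + 1
            rng.shuffle(labels)
            de_idx = rng.choice(self.n_probes, size=n_de, replace=False)
            archetypes[de_idx] = labels
            for idx, lab in zip(de_idx, labels):
                r01, r13, r4, r5 = ARCHETYPE_PROFILES[int(lab)]
                jit = rng.normal(0.0, self.archetype_jitter_sd, size=4)
                r.iloc[idx] = [r01 + jit[0], r13 + jit[1], 0.0, r4 + jit[2], r5 + jit[3]]
        r["0v3"] = r["0v1"] + r["1v3"]
        r.attrs["archetype"] = pd.Series(archetypes, index=probes)
        return r


def generate_microarray_set(
    design_labels: list[str] | None = None,
    truth: ArrayTruth | None = None,
    seed: int = 0,
) -> tuple[list[TwoChannelArray], pd.DataFrame]:
    """Generate two-channel spot tables for the requested designs.

    Loop designs (0v1, 1v3, 0v3) are generated in triplicate, reference
    designs ('4', '5') singly.  Returns the arrays plus the per-probe true
    log2-ratio table (one column per design label).
    """
    truth = truth or ArrayTruth()
    labels = design_labels or ["0v1", "1v3", "0v3", "4", "5"]
    known = set(LOOP_DESIGNS) | set(REFERENCE_DESIGNS)
    for lab in labels:
        if lab not in known:
            raise ValueError(f"unknown design label {lab!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B07]))
    ratios = truth.true_ratios(seed)
    probes = list(ratios.index)
    base = rng.normal(truth.base_log2_mean, truth.base_log2_sd, size=truth.n_probes)

    arrays: list[TwoChannelArray] = []
    for lab in labels:
        n_rep = 3 if lab in LOOP_DESIGNS else 1
        r_true = ratios[lab].to_numpy()
        for rep in range(1, n_rep + 1):
            eps = rng.normal(0.0, truth.spot_noise_sd, size=(4, truth.n_probes))
            bg_g = truth.background_level * 2.0 ** eps[0]
            bg_r = truth.background_level * 2.0 ** eps[1]
            f_g = bg_g * 2.0 ** (base + eps[2])
            f_r = bg_r * 2.0 ** (base + r_true + eps[3])
            arrays.append(
                TwoChannelArray(
                    probe_id=probes,
                    f_r=f_r,
                    b_r=bg_r,
                    f_g=f_g,
                    b_g=bg_g,
                    replicate=rep,
                    design=lab,
                )
            )
    return arrays, ratios
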