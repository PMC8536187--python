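"""Synthetic ICU event generator with exactly recoverable planted truth.

Emits the five MIMIC-shaped tables (stays, labs, repletions, diagnoses and
a demographics view folded into stays) from a fully specified generative
model, together with closed-form expectations for every quantity the audit
pipeline measures, so the whole pipeline can be validated end-to-end
without any data download.

Generative model (per stay, per electrolyte, per *draw cluster*):

* cluster times sit on a circadian clock-hour mixture (major morning peak,
  minor evening peak) on days spaced ``slot_spacing_hours`` apart;
* the serum value ``v`` is truncated-normal within the physiologic error
  bounds (mean shiftable per ICU unit);
* a repletion order fires with probability ``base * sigmoid((theta - v)/s)``
  — a fuzzy threshold rule — at the cluster's draw time plus a lognormal
  latency truncated at the 24-h window;
* with probability ``scenario_mix`` an extra non-triggering draw precedes
  the index draw inside the window (producing a multi-lab ML->1R episode);
* a follow-up draw occurs after the order (lognormal delay, truncated at
  the window) with value ``v + post_shift + noise``, the noise truncated so
  the value stays physiologic;
* planted minors, excluded first diagnoses and out-of-bounds error values
  are inserted in exactly known counts.

Clusters are spaced far enough apart (validated at construction) that
linkage output is exactly predictable: extra draws are always consumed as
ignored labs, follow-up draws always re-enter the pool as NR episodes, and
no window spans two clusters.  Every :class:`PlantedTruth` expectation is
then a one-dimensional quadrature over the value distribution — including
the subtlety that the episode-level repletion fraction is ``p/(1+p)`` when
each follow-up draw re-enters the NR pool (``p`` the per-cluster trigger
probability).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.special import expit

from .errors import ConfigError
from .model import ELECTROLYTES, ICU_UNITS, VALUE_UNITS, default_error_bounds
from . import io as raio

_EXTRA_MIN = 60.0    # extra (ML) draw precedes the index draw by 1-6 h
_EXTRA_MAX = 360.0

#: Benign first-diagnosis codes for clean stays (must not prefix-match any
#: default exclusion set).
_BENIGN = ("4019", "486", "0389", "5070", "431", "51881", "2449", "3051")
#: Excluded first-diagnosis codes planted on the excluded-dx stays.
_PLANT_DX = ("42731", "4280", "5856", "5845", "41401", "2521", "135")


@dataclass(frozen=True)
class ElectrolyteParams:
    """Per-electrolyte generative settings (units: native serum units, minutes)."""

    mean: float
    sd: float
    base_prob: float          # repletion probability plateau for very low values
    threshold: float          # logistic midpoint of the repletion rule
    slope: float              # logistic softness (same units as the value)
    latency_meanlog: float    # lab-to-order lognormal, log-minutes
    latency_sdlog: float
    followup_meanlog: float   # order-to-follow-up lognormal, log-minutes
    followup_sdlog: float
    post_shift: float         # additive serum shift attributed to repletion
    post_noise_sd: float
    dose: float
    dose_unit: str


def _default_electrolytes() -> dict[str, ElectrolyteParams]:
    # Latency log-means place the (untruncated) lognormal means near the
    # workflow latencies the audit reports on real ICU data (~217/323/340
    # min draw-to-order; ~443/643/567 min order-to-follow-up); post shifts
    # are 0.32/1.08/0.87 population SDs so the demo effect sizes land in
    # the small/large/large bands.
    return {
        "potassium": ElectrolyteParams(
            mean=4.0, sd=0.45, base_prob=0.11, threshold=3.7, slope=0.30,
            latency_meanlog=4.9759, latency_sdlog=0.9,
            followup_meanlog=5.6896, followup_sdlog=0.9,
            post_shift=0.32 * 0.45, post_noise_sd=0.22,
            dose=40.0, dose_unit="mEq",
        ),
        "magnesium": ElectrolyteParams(
            mean=3.0, sd=0.45, base_prob=0.50, threshold=2.5, slope=0.30,
            latency_meanlog=5.3736, latency_sdlog=0.9,
            followup_meanlog=6.0613, followup_sdlog=0.9,
            post_shift=1.08 * 0.45, post_noise_sd=0.22,
            dose=2.0, dose_unit="g",
        ),
        "phosphate": ElectrolyteParams(
            mean=3.0, sd=0.55, base_prob=0.85, threshold=2.5, slope=0.30,
            latency_meanlog=5.4235, latency_sdlog=0.9,
            followup_meanlog=5.9357, followup_sdlog=0.9,
            post_shift=0.87 * 0.55, post_noise_sd=0.28,
            dose=15.0, dose_unit="mmol",
        ),
    }


@dataclass(frozen=True)
class GeneratorParams:
    """Full description of the synthetic study conditions."""

    n_stays: int = 1000
    labs_per_stay_mean: float = 3.0   # draw clusters per stay per electrolyte
    circadian_peaks: tuple[float, float] = (6.0, 18.0)
    circadian_weights: tuple[float, float] = (0.7, 0.3)
    circadian_sd_hours: float = 1.5
    scenario_mix: float = 0.489       # target ML->1R share among repletions
    window_minutes: float = 1440.0
    slot_spacing_hours: float = 96.0
    minor_fraction: float = 0.01
    excluded_dx_fraction: float = 0.05
    error_value_fraction: float = 0.002
    unit_probs: dict = field(
        default_factory=lambda: {
            "MICU": 0.30, "SICU": 0.25, "CICU": 0.20, "HVICU": 0.15, "other": 0.10
        }
    )
    unit_value_offsets: dict = field(default_factory=dict)  # {unit: {elec: shift}}
    electrolytes: dict = field(default_factory=_default_electrolytes)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stays < 1:
            raise ConfigError("n_stays must be >= 1")
        for p in (
            self.scenario_mix, self.minor_fraction,
            self.excluded_dx_fraction, self.error_value_fraction,
            *self.circadian_weights,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if abs(sum(self.circadian_weights) - 1.0) > 1e-9:
            raise ConfigError("circadian weights must sum to 1")
        if self.circadian_sd_hours <= 0:
            raise ConfigError("circadian_sd_hours must be > 0")
        for elec, ep in self.electrolytes.items():
            if elec not in ELECTROLYTES:
                raise ConfigError(f"unknown electrolyte {elec!r}")
            if ep.sd <= 0 or ep.post_noise_sd <= 0:
                raise ConfigError(f"{elec}: standard deviations must be > 0")
            if not 0.0 <= ep.base_prob <= 1.0:
                raise ConfigError(f"{elec}: base_prob outside [0, 1]")
        # cluster isolation: with extras enabled, consecutive clusters must
        # be far enough apart that no 24-h window can span two clusters
        # (spacing > 2*window + extra-draw lead + one day of clock jitter);
        # otherwise the planted expectations would not be exact.
        needed = 2 * self.window_minutes + _EXTRA_MAX + 24 * 60
        if self.scenario_mix > 0 and self.slot_spacing_hours * 60 <= needed:
            raise ConfigError(
                "slot_spacing_hours too small for an isolated multi-lab window: "
                f"need > {needed / 60:.1f} h, got {self.slot_spacing_hours} h "
                "(a 24-h look-back plus 24-h follow-up plus extra-draw lead "
                "plus clock jitter must fit between clusters)"
            )

    # deterministic planted counts -------------------------------------
    @property
    def n_minor_stays(self) -> int:
        return int(round(self.n_stays * self.minor_fraction))

    @property
    def n_excluded_dx_stays(self) -> int:
        return int(round(self.n_stays * self.excluded_dx_fraction))

    @property
    def n_error_values(self) -> int:
        return int(
            round(self.n_stays * len(self.electrolytes) * self.labs_per_stay_mean
                  * self.error_value_fraction)
        )


@dataclass
class PlantedTruth:
    """Closed-form expectations for every audited quantity.

    ``repletion_fraction`` is the *episode-level* expectation p/(1+p) the
    pipeline measures (follow-up draws re-enter the NR pool);
    ``trigger_prob`` is the raw per-cluster probability p.  Cell
    proportions are keyed ``(electrolyte, group, label)`` with groups
    ``repletion``/``non_repletion`` and labels below/within/above.
    """

    trigger_prob: dict = field(default_factory=dict)
    repletion_fraction: dict = field(default_factory=dict)
    ml_fraction: dict = field(default_factory=dict)
    cell_proportions: dict = field(default_factory=dict)
    d_expected: dict = field(default_factory=dict)
    pre_mean: dict = field(default_factory=dict)
    post_mean: dict = field(default_factory=dict)
    latency_mean: dict = field(default_factory=dict)
    followup_latency_mean: dict = field(default_factory=dict)
    peak_hour: int = 6
    n_minor_stays: int = 0
    n_excluded_dx_stays: int = 0
    n_error_values: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["cell_proportions"] = {
            f"{e}/{g}/{label}": v for (e, g, label), v in self.cell_proportions.items()
        }
        return json.dumps(d, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# quadrature helpers

def _trunc_moments(alpha: np.ndarray, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance factors of a standard normal truncated to [alpha, beta]."""
    z = sps.norm.cdf(beta) - sps.norm.cdf(alpha)
    z = np.maximum(z, 1e-300)
    pa, pb = sps.norm.pdf(alpha), sps.norm.pdf(beta)
    m = (pa - pb) / z
    v = 1.0 + (alpha * pa - beta * pb) / z - m**2
    return m, v


def _value_density(params: GeneratorParams, elec: str, grid: np.ndarray) -> np.ndarray:
    """Marginal density of clean serum values (unit-mixture truncated normal)."""
    ep = params.electrolytes[elec]
    low, high = default_error_bounds()[elec]
    dens = np.zeros_like(grid)
    for unit, w in params.unit_probs.items():
        loc = ep.mean + params.unit_value_offsets.get(unit, {}).get(elec, 0.0)
        a, b = (low - loc) / ep.sd, (high - loc) / ep.sd
        dens += w * sps.truncnorm.pdf(grid, a, b, loc=loc, scale=ep.sd)
    return dens


def _trunc_lognorm_mean(meanlog: float, sdlog: float, upper: float) -> float:
    """Mean of a lognormal truncated to (0, upper]."""
    z = sps.norm.cdf((np.log(upper) - meanlog) / sdlog)
    z_shift = sps.norm.cdf((np.log(upper) - meanlog - sdlog**2) / sdlog)
    return float(np.exp(meanlog + 0.5 * sdlog**2) * z_shift / z)


def planted_truth(
    params: GeneratorParams, ranges: dict | None = None, n_grid: int = 4001
) -> PlantedTruth:
    """Closed-form (quadrature) expectations under ``params``.

    ``ranges`` maps electrolytes to :class:`ReferenceRange`; defaults to
    the nominal ranges.  All integrals are over the truncated-normal value
    density on an ``n_grid``-point grid (trapezoid rule, error ~1e-8).
    """
    from .model import default_reference_ranges

    ranges = ranges if ranges is not None else default_reference_ranges()
    truth = PlantedTruth(
        peak_hour=int(params.circadian_peaks[int(np.argmax(params.circadian_weights))]),
        n_minor_stays=params.n_minor_stays,
        n_excluded_dx_stays=params.n_excluded_dx_stays,
        n_error_values=params.n_error_values,
    )
    bounds = default_error_bounds()
    w = params.window_minutes
    for elec, ep in params.electrolytes.items():
        low_b, high_b = bounds[elec]
        grid = np.linspace(low_b, high_b, n_grid)
        f = _value_density(params, elec, grid)
        p_v = ep.base_prob * expit((ep.threshold - grid) / ep.slope)
        p_bar = float(np.trapezoid(f * p_v, grid))
        truth.trigger_prob[elec] = p_bar
        truth.repletion_fraction[elec] = p_bar / (1.0 + p_bar)

        # extras are only planted when the order latency leaves room for the
        # 1-6 h lead inside the window
        lat_cdf_w = sps.lognorm.cdf(w, ep.latency_sdlog, scale=np.exp(ep.latency_meanlog))
        lat_cdf_ok = sps.lognorm.cdf(
            w - _EXTRA_MAX, ep.latency_sdlog, scale=np.exp(ep.latency_meanlog)
        )
        truth.ml_fraction[elec] = params.scenario_mix * float(lat_cdf_ok / lat_cdf_w)

        # repletion-group (index value) conditional density
        if p_bar > 0:
            f_rep = f * p_v / p_bar
        else:
            f_rep = np.zeros_like(f)
        mu_c = float(np.trapezoid(grid * f_rep, grid))
        var_c = float(np.trapezoid(grid**2 * f_rep, grid)) - mu_c**2

        # post value: g + truncated noise keeping the value physiologic
        g = grid + ep.post_shift
        alpha, beta = (low_b - g) / ep.post_noise_sd, (high_b - g) / ep.post_noise_sd
        m_fac, v_fac = _trunc_moments(alpha, beta)
        post_mean_v = g + ep.post_noise_sd * m_fac
        post_var_v = ep.post_noise_sd**2 * v_fac
        mu_post = float(np.trapezoid(post_mean_v * f_rep, grid))
        e_post2 = float(np.trapezoid((post_var_v + post_mean_v**2) * f_rep, grid))
        var_post = e_post2 - mu_post**2
        truth.pre_mean[elec] = mu_c
        truth.post_mean[elec] = mu_post
        truth.d_expected[elec] = (
            (mu_post - mu_c) / np.sqrt((var_c + var_post) / 2.0) if p_bar > 0 else 0.0
        )

        # interpretation-cell proportions
        rng_ = ranges[elec]
        lo_i = grid < rng_.low if rng_.low_inclusive else grid <= rng_.low
        hi_i = grid > rng_.high if rng_.high_inclusive else grid >= rng_.high
        mid_i = ~lo_i & ~hi_i

        def _mass(dens: np.ndarray, mask: np.ndarray) -> float:
            return float(np.trapezoid(np.where(mask, dens, 0.0), grid))

        # NR pool = untriggered primaries + follow-up draws (weights 1-p, p)
        f_un = f * (1.0 - p_v)
        # P(post in region | pre) via the truncated-noise CDF
        z_fac = np.maximum(sps.norm.cdf(beta) - sps.norm.cdf(alpha), 1e-300)

        def _post_cdf(c: float) -> np.ndarray:
            arg = (c - g) / ep.post_noise_sd
            return np.clip((sps.norm.cdf(arg) - sps.norm.cdf(alpha)) / z_fac, 0.0, 1.0)

        p_post_below = float(np.trapezoid(_post_cdf(rng_.low) * f_rep, grid))
        p_post_within = float(np.trapezoid(_post_cdf(rng_.high) * f_rep, grid)) - p_post_below
        p_post_above = max(0.0, 1.0 - p_post_below - p_post_within)

        nr_norm = (1.0 - p_bar) + p_bar
        for label, mask, p_post in (
            ("below", lo_i, p_post_below),
            ("within", mid_i, p_post_within),
            ("above", hi_i, p_post_above),
        ):
            truth.cell_proportions[(elec, "repletion", label)] = _mass(f_rep, mask)
            truth.cell_proportions[(elec, "non_repletion", label)] = (
                _mass(f_un, mask) + p_bar * p_post
            ) / nr_norm

        truth.latency_mean[elec] = _trunc_lognorm_mean(ep.latency_meanlog, ep.latency_sdlog, w)
        truth.followup_latency_mean[elec] = _trunc_lognorm_mean(
            ep.followup_meanlog, ep.followup_sdlog, w
        )
    return truth


# ---------------------------------------------------------------------------
# generation

def _circadian_hours(params: GeneratorParams, n: int, rng: np.random.Generator) -> np.ndarray:
    # peaks denote clock hours ("the 06:00 draw"); center each component at
    # the middle of its hour so the peak's histogram bin is unambiguous
    comp = rng.random(n) < params.circadian_weights[0]
    peak = np.where(comp, params.circadian_peaks[0], params.circadian_peaks[1])
    return (peak + 0.5 + rng.normal(0.0, params.circadian_sd_hours, n)) % 24.0


def _trunc_lognorm_ppf(u: np.ndarray, meanlog: float, sdlog: float, upper: float) -> np.ndarray:
    scale = np.exp(meanlog)
    f_upper = sps.lognorm.cdf(upper, sdlog, scale=scale)
    return sps.lognorm.ppf(u * f_upper, sdlog, scale=scale)


def generate_cohort(
    params: GeneratorParams, out_dir: str | os.PathLike | None = None
) -> tuple[dict[str, pd.DataFrame], PlantedTruth]:
    """Generate the event tables (and optionally write them as CSV).

    Returns ``(tables, truth)`` where ``tables`` holds canonical-schema
    ``stays``, ``labs``, ``repletions`` and ``diagnoses`` frames.  Output
    is deterministic given ``params.seed``: identical parameters produce
    byte-identical CSVs.
    """
    rng = np.random.default_rng(params.seed)
    bounds = default_error_bounds()
    elec_names = list(params.electrolytes)
    n_clean = params.n_stays
    n_minor = params.n_minor_stays
    n_dx = params.n_excluded_dx_stays
    n_total = n_clean + n_minor + n_dx

    # ---- stays ---------------------------------------------------------
    stay_ids = np.array([f"S{i:06d}" for i in range(n_total)])
    subject_ids = np.array([f"P{i:06d}" for i in range(n_total)])
    units = rng.choice(
        list(params.unit_probs), p=list(params.unit_probs.values()), size=n_total
    )
    ages = rng.uniform(18.5, 90.0, n_total)
    if n_minor:
        ages[n_clean : n_clean + n_minor] = rng.uniform(1.0, 17.5, n_minor)
    weights = np.clip(rng.normal(80.0, 15.0, n_total), 35.0, 200.0)
    base_minute = int(pd.Timestamp("2140-01-01").value // 60_000_000_000)
    intime = base_minute + rng.integers(0, 1095, n_total) * 1440 + rng.integers(0, 1440, n_total)

    # ---- diagnoses -----------------------------------------------------
    first_codes = rng.choice(_BENIGN, size=n_total)
    if n_dx:
        first_codes[n_clean + n_minor :] = rng.choice(_PLANT_DX, size=n_dx)
    dx_rows = [
        pd.DataFrame(
            {"subject_id": subject_ids, "stay_id": stay_ids, "icd9_code": first_codes,
             "seq_num": 1}
        )
    ]
    # secondary diagnoses, some deliberately in excluded sets: the cascade
    # must ignore anything past seq_num 1
    has_second = rng.random(n_total) < 0.5
    second = np.where(rng.random(n_total) < 0.1, "4280", rng.choice(_BENIGN, size=n_total))
    dx_rows.append(
        pd.DataFrame(
            {
                "subject_id": subject_ids[has_second],
                "stay_id": stay_ids[has_second],
                "icd9_code": second[has_second],
                "seq_num": 2,
            }
        )
    )
    diagnoses = pd.concat(dx_rows, ignore_index=True)

    # ---- draw clusters -------------------------------------------------
    mean_extra = max(params.labs_per_stay_mean - 1.0, 0.0)
    n_slots = 1 + rng.poisson(mean_extra, size=(n_total, len(elec_names)))
    stay_rep, elec_rep = [], []
    for j in range(len(elec_names)):
        stay_rep.append(np.repeat(np.arange(n_total), n_slots[:, j]))
        elec_rep.append(np.full(n_slots[:, j].sum(), j))
    slot_stay = np.concatenate(stay_rep)
    slot_elec = np.concatenate(elec_rep)
    slot_k = np.concatenate(
        [np.concatenate([np.arange(k) for k in n_slots[:, j]]) for j in range(len(elec_names))]
    )
    n_slot = len(slot_stay)

    spacing_min = int(round(params.slot_spacing_hours * 60))
    day_anchor = (intime[slot_stay] // 1440) * 1440 + (slot_k + 1) * spacing_min
    hours = _circadian_hours(params, n_slot, rng)
    slot_t = day_anchor + np.round(hours * 60.0).astype(np.int64)

    # serum values: truncated normal within physiologic bounds, unit-shifted
    offsets = np.zeros(n_slot)
    locs = np.zeros(n_slot)
    scales = np.zeros(n_slot)
    low_arr = np.zeros(n_slot)
    high_arr = np.zeros(n_slot)
    for j, elec in enumerate(elec_names):
        ep = params.electrolytes[elec]
        sel = slot_elec == j
        off = np.array(
            [params.unit_value_offsets.get(u, {}).get(elec, 0.0) for u in units[slot_stay[sel]]]
        )
        locs[sel] = ep.mean + off
        scales[sel] = ep.sd
        low_arr[sel], high_arr[sel] = bounds[elec]
        offsets[sel] = off
    a = (low_arr - locs) / scales
    b = (high_arr - locs) / scales
    values = sps.truncnorm.ppf(rng.random(n_slot), a, b, loc=locs, scale=scales)

    # repletion decisions: fuzzy logistic threshold on the value
    p_fire = np.zeros(n_slot)
    for j, elec in enumerate(elec_names):
        ep = params.electrolytes[elec]
        sel = slot_elec == j
        p_fire[sel] = ep.base_prob * expit((ep.threshold - values[sel]) / ep.slope)
    fired = rng.random(n_slot) < p_fire

    lat = np.zeros(n_slot)
    fu_delay = np.zeros(n_slot)
    u_lat = rng.random(n_slot)
    u_fu = rng.random(n_slot)
    for j, elec in enumerate(elec_names):
        ep = params.electrolytes[elec]
        sel = slot_elec == j
        lat[sel] = _trunc_lognorm_ppf(
            u_lat[sel], ep.latency_meanlog, ep.latency_sdlog, params.window_minutes
        )
        fu_delay[sel] = _trunc_lognorm_ppf(
            u_fu[sel], ep.followup_meanlog, ep.followup_sdlog, params.window_minutes
        )
    lat_r = np.maximum(1, np.round(lat)).astype(np.int64)
    fu_r = np.maximum(1, np.round(fu_delay)).astype(np.int64)
    order_t = slot_t + lat_r
    fu_t = order_t + fu_r

    # extra (multi-lab) draws: planted only when the latency leaves room
    # for the 1-6 h lead inside the look-back window
    u_extra = rng.random(n_slot)
    extra_lead = np.round(rng.uniform(_EXTRA_MIN, _EXTRA_MAX, n_slot)).astype(np.int64)
    has_extra = fired & (u_extra < params.scenario_mix) & (
        lat_r <= params.window_minutes - _EXTRA_MAX
    )
    extra_vals = sps.truncnorm.ppf(rng.random(n_slot), a, b, loc=locs, scale=scales)

    # follow-up values: pre + shift + truncated noise (stays physiologic)
    post_shift = np.zeros(n_slot)
    noise_sd = np.zeros(n_slot)
    for j, elec in enumerate(elec_names):
        ep = params.electrolytes[elec]
        sel = slot_elec == j
        post_shift[sel] = ep.post_shift
        noise_sd[sel] = ep.post_noise_sd
    g = values + post_shift
    na = (low_arr - g) / noise_sd
    nb = (high_arr - g) / noise_sd
    fu_vals = sps.truncnorm.ppf(rng.random(n_slot), na, nb, loc=g, scale=noise_sd)

    # ---- assemble lab rows --------------------------------------------
    elec_label = np.array(elec_names, dtype=object)[slot_elec]

    def _lab_frame(mask: np.ndarray, t: np.ndarray, v: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": subject_ids[slot_stay[mask]],
                "stay_id": stay_ids[slot_stay[mask]],
                "electrolyte": elec_label[mask],
                "charttime": t[mask],
                "value": v[mask],
            }
        )

    all_mask = np.ones(n_slot, dtype=bool)
    labs_parts = [
        _lab_frame(all_mask, slot_t, values),
        _lab_frame(has_extra, slot_t - extra_lead, extra_vals),
        _lab_frame(fired, fu_t, fu_vals),
    ]

    # planted out-of-bounds error values on random clean stays
    n_err = params.n_error_values
    if n_err:
        err_stay = rng.integers(0, n_clean, n_err)
        err_elec = rng.integers(0, len(elec_names), n_err)
        err_t = intime[err_stay] + rng.integers(60, 5 * 1440, n_err)
        lo = np.array([bounds[elec_names[j]][0] for j in err_elec])
        hi = np.array([bounds[elec_names[j]][1] for j in err_elec])
        go_low = rng.random(n_err) < 0.5
        err_v = np.where(
            go_low,
            rng.uniform(0.5 * lo, 0.95 * lo),
            rng.uniform(1.02 * hi + 0.05, 1.4 * hi),
        )
        labs_parts.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids[err_stay],
                    "stay_id": stay_ids[err_stay],
                    "electrolyte": np.array(elec_names, dtype=object)[err_elec],
                    "charttime": err_t,
                    "value": err_v,
                }
            )
        )

    labs = pd.concat(labs_parts, ignore_index=True)
    labs["charttime"] = pd.to_datetime(labs["charttime"], unit="m")
    labs["value_unit"] = labs["electrolyte"].map(VALUE_UNITS)
    labs = labs.sort_values(
        ["stay_id", "electrolyte", "charttime", "value"], kind="mergesort"
    ).reset_index(drop=True)

    # ---- repletions ----------------------------------------------------
    dose = np.zeros(n_slot)
    dose_unit = np.empty(n_slot, dtype=object)
    for j, elec in enumerate(elec_names):
        ep = params.electrolytes[elec]
        sel = slot_elec == j
        dose[sel] = ep.dose
        dose_unit[sel] = ep.dose_unit
    repletions = pd.DataFrame(
        {
            "subject_id": subject_ids[slot_stay[fired]],
            "stay_id": stay_ids[slot_stay[fired]],
            "electrolyte": elec_label[fired],
            "ordertime": pd.to_datetime(order_t[fired], unit="m"),
            "dose": dose[fired],
            "dose_unit": dose_unit[fired],
            "route": "IV",
        }
    ).sort_values(["stay_id", "electrolyte", "ordertime"], kind="mergesort").reset_index(drop=True)

    # ---- stay table (outtime covers every event) ----------------------
    last_event = np.full(n_total, -1, dtype=np.int64)
    np.maximum.at(last_event, slot_stay, fu_t)  # follow-ups are the latest per slot
    last_event = np.maximum(last_event, intime + 6 * 1440)  # cover injected error rows too
    stays = pd.DataFrame(
        {
            "stay_id": stay_ids,
            "subject_id": subject_ids,
            "unit_type": units,
            "intime": pd.to_datetime(intime, unit="m"),
            "outtime": pd.to_datetime(last_event + 1440, unit="m"),
            "age_years": np.round(ages, 1),
            "weight_kg": np.round(weights, 1),
        }
    )

    tables = {"stays": stays, "labs": labs, "repletions": repletions, "diagnoses": diagnoses}
    truth = planted_truth(params)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for name, df in tables.items():
            raio.write_summary_table(df, os.path.join(out_dir, f"{name}.csv"))
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            fh.write(truth.to_json())
    return tables, truth
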