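"""Synthetic matched NIRS-IVUS / CTA cohorts with known ground truth.

No patient imaging from the motivating trial design is publicly available,
so every downstream stage is exercised on simulated cohorts that emulate
its statistical structure:

* per-subject random effects on log vessel size and plaque burden;
* smooth longitudinal profiles (AR(1) on the log/logit scale) so that
  plaque-burden runs are contiguous, as the lesion definition requires;
* zero-inflated, within-vessel-persistent calcium areas (two-state Markov
  calcified/non-calcified states with gamma-distributed run levels);
* paired modality measurements with multiplicative (log-scale) noise and a
  calcium-dependent CTA bias: measured lumen and plaque areas are the true
  areas times exp(delta0 + delta1 * ca_area) times lognormal noise, so the
  bias scales with vessel size;
* patchy lipid and calcium circumferential arcs that persist along the
  pullback (Markov on/off states with slowly drifting arc centre and
  width).

All randomness flows from the mandatory ``seed``; regenerating with the
same spec is byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_N_BINS,
    Frame,
    MatchedDataset,
    Modality,
    Tissue,
)

__all__ = [
    "SyntheticCohortSpec",
    "generate_cohort",
    "scenario_presets",
    "two_way_table",
    "interaction_sample",
]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative parameters of one synthetic cohort.

    Log-area scale parameters (``subject_sd``, ``modality_shift``,
    ``residual_sd``, the ``delta`` bias coefficients) act multiplicatively
    on areas. ``delta1_*`` are per mm^2 of calcium area.
    """

    n_subjects: int = 64
    vessels_per_subject: int = 3
    frames_per_segment: int = 120
    frame_spacing: float = 0.5  # mm

    # vessel geometry (log scale)
    log_vessel_mu: float = 2.55  # exp -> ~12.8 mm^2 vessel area
    subject_sd: float = 0.35
    ar1_rho: float = 0.9
    ar1_sd: float = 0.15

    # plaque burden (logit scale)
    pb_logit_mu: float = -0.5  # expit -> ~38% mean plaque fraction
    pb_subject_sd: float = 0.35
    pb_ar1_sd: float = 0.45

    # modality and residual noise (log-area scale)
    modality_shift: float = 0.02  # SD of the random modality intercept
    residual_sd: float = 0.08

    # CTA bias coefficients (log-area scale)
    delta0: float = -0.45  # baseline log-bias of CTA plaque area
    delta1: float = 0.04  # calcium-dependent log-bias per mm^2 Ca
    lumen_delta0: float = -0.28
    lumen_delta1: float = -0.01  # blooming shrinks the CTA lumen with Ca

    # calcium model
    ca_zero_inflation: float = 0.6  # stationary fraction of Ca-free frames
    ca_persistence: float = 0.92  # stay-probability of the calcified state
    ca_gamma_shape: float = 1.5
    ca_gamma_scale: float = 1.6  # mm^2

    # lipid patches
    lipid_patch_rate: float = 0.06  # off -> on probability per frame
    lipid_persistence: float = 0.9  # on -> on probability per frame

    n_bins: int = DEFAULT_N_BINS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subject_sd", "pb_subject_sd", "residual_sd", "ar1_sd",
                     "pb_ar1_sd", "modality_shift"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ca_zero_inflation", "ca_persistence",
                     "lipid_patch_rate", "lipid_persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def scenario_presets() -> dict[str, SyntheticCohortSpec]:
    """Named cohort scenarios.

    null
        No modality bias and no calcium-dependent bias: interaction tests
        should reject at their nominal level and the true biases are zero.
    paper-like
        Cohort dimensions echoing the motivating study design: 64
        subjects, 3 vessels each, ~120 matched frames per vessel
        (~23,000 matched cross-sections in total).
    high-calcium
        Heavily calcified cohort (few calcium-free frames, larger Ca
        areas).
    """
    return {
        "null": SyntheticCohortSpec(
            n_subjects=32,
            vessels_per_subject=2,
            frames_per_segment=60,
            delta0=0.0,
            delta1=0.0,
            lumen_delta0=0.0,
            lumen_delta1=0.0,
            modality_shift=0.0,
        ),
        "paper-like": SyntheticCohortSpec(),
        "high-calcium": SyntheticCohortSpec(
            ca_zero_inflation=0.2,
            ca_gamma_scale=3.0,
            ca_persistence=0.95,
        ),
    }


def get_preset(name: str) -> SyntheticCohortSpec:
    presets = scenario_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path with marginal SD ``sd``."""
    x = np.empty(n)
    innov_sd = sd * np.sqrt(1 - rho**2)
    x[0] = rng.normal(0, sd)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + rng.normal(0, innov_sd)
    return x


def _markov_states(rng: np.random.Generator, n: int, stay_on: float,
                   frac_on: float) -> np.ndarray:
    """Two-state Markov chain with stationary on-fraction ``frac_on``."""
    if frac_on <= 0:
        return np.zeros(n, dtype=bool)
    if frac_on >= 1:
        return np.ones(n, dtype=bool)
    # stationary fraction pi = p_on / (p_on + p_off) with transition
    # probabilities p_on = P(off->on), p_off = P(on->off) = 1 - stay_on
    p_off = 1.0 - stay_on
    p_on = min(1.0, p_off * frac_on / (1.0 - frac_on))
    s = np.empty(n, dtype=bool)
    s[0] = rng.random() < frac_on
    u = rng.random(n)
    for t in range(1, n):
        s[t] = (u[t] < stay_on) if s[t - 1] else (u[t] < p_on)
    return s


def _arc_mask(center_deg: float, width_deg: float, n_bins: int) -> np.ndarray:
    """Boolean mask of a circular arc."""
    deg = (np.arange(n_bins) + 0.5) * 360.0 / n_bins
    half = width_deg / 2.0
    d = np.abs((deg - center_deg + 180.0) % 360.0 - 180.0)
    return d <= half


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[MatchedDataset, dict]:
    """Generate one matched cohort plus its ground-truth record.

    Returns ``(dataset, truth)`` where ``truth`` carries the spec, the
    modality random intercepts, and a per-frame table of latent true
    areas (lumen, plaque, calcium).
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.frames_per_segment
    positions = np.arange(n_frames) * spec.frame_spacing

    m_nirs, m_cta = rng.normal(0.0, spec.modality_shift, size=2)
    pairs: list[tuple[Frame, Frame]] = []
    truth_rows = []

    for si in range(spec.n_subjects):
        subject = f"S{si:03d}"
        b_size = rng.normal(0, spec.subject_sd)
        b_pb = rng.normal(0, spec.pb_subject_sd)
        for vi in range(spec.vessels_per_subject):
            vessel = f"V{vi}"
            log_vessel = spec.log_vessel_mu + b_size + _ar1(
                rng, n_frames, spec.ar1_rho, spec.ar1_sd
            )
            vessel_true = np.exp(log_vessel)
            pb_frac = 1.0 / (1.0 + np.exp(-(spec.pb_logit_mu + b_pb + _ar1(
                rng, n_frames, spec.ar1_rho, spec.pb_ar1_sd
            ))))
            plaque_true = pb_frac * vessel_true
            lumen_true = vessel_true - plaque_true

            # calcium: persistent on/off state, gamma level per run with
            # smooth within-run modulation, capped below the plaque area
            ca_state = _markov_states(
                rng, n_frames, spec.ca_persistence, 1.0 - spec.ca_zero_inflation
            )
            ca_true = np.zeros(n_frames)
            t = 0
            while t < n_frames:
                if ca_state[t]:
                    run_end = t
                    while run_end + 1 < n_frames and ca_state[run_end + 1]:
                        run_end += 1
                    level = rng.gamma(spec.ca_gamma_shape, spec.ca_gamma_scale)
                    mod = np.exp(_ar1(rng, run_end - t + 1, 0.8, 0.25))
                    ca_true[t : run_end + 1] = level * mod
                    t = run_end + 1
                else:
                    t += 1
            ca_true = np.minimum(ca_true, 0.9 * plaque_true)

            # lipid patches: Markov on/off with drifting arc centre/width
            lipid_on = _markov_states(
                rng,
                n_frames,
                spec.lipid_persistence,
                spec.lipid_patch_rate
                / max(1e-9, spec.lipid_patch_rate + (1 - spec.lipid_persistence)),
            )
            lipid_center = (rng.uniform(0, 360) + np.cumsum(
                rng.normal(0, 8, n_frames)
            )) % 360
            lipid_width = np.clip(
                rng.uniform(40, 120) + np.cumsum(rng.normal(0, 4, n_frames)), 20, 160
            )
            ca_center = (rng.uniform(0, 360) + np.cumsum(
                rng.normal(0, 6, n_frames)
            )) % 360

            # modality measurements (multiplicative noise and CTA bias)
            eps = rng.normal(0, spec.residual_sd, size=(4, n_frames))
            lumen_nirs = lumen_true * np.exp(m_nirs + eps[0])
            plaque_nirs = plaque_true * np.exp(m_nirs + eps[1])
            lumen_cta = lumen_true * np.exp(
                m_cta + spec.lumen_delta0 + spec.lumen_delta1 * ca_true + eps[2]
            )
            plaque_cta = plaque_true * np.exp(
                m_cta + spec.delta0 + spec.delta1 * ca_true + eps[3]
            )
            ca_cta = ca_true * np.exp(rng.normal(0.05, 0.15, n_frames))
            ca_cta = np.where(ca_true > 0, np.minimum(ca_cta, 0.95 * plaque_cta), 0.0)

            for j in range(n_frames):
                nirs_bins = np.zeros(spec.n_bins, dtype=np.uint8)
                cta_bins = np.zeros(spec.n_bins, dtype=np.uint8)
                # fibrotic background wherever plaque exists
                pb_j = plaque_true[j] / vessel_true[j]
                if pb_j > 0.2:
                    ft_arc = _arc_mask(
                        float(lipid_center[j] + 180) % 360,
                        min(340.0, 360 * pb_j),
                        spec.n_bins,
                    )
                    nirs_bins[ft_arc] |= int(Tissue.FT)
                    cta_bins[ft_arc] |= int(Tissue.FT)
                if lipid_on[j]:
                    arc = _arc_mask(lipid_center[j], lipid_width[j], spec.n_bins)
                    nirs_bins[arc] |= int(Tissue.LIPID)
                    # CTA sees attenuated lipid, increasingly masked by Ca
                    detect = rng.random() < 1.0 / (1.0 + 0.15 * ca_true[j])
                    if detect:
                        w = lipid_width[j] * np.exp(rng.normal(-0.1, 0.25))
                        cta_bins[
                            _arc_mask(lipid_center[j], min(340.0, w), spec.n_bins)
                        ] |= int(Tissue.LIPID)
                if ca_true[j] > 0:
                    frac = min(0.9, ca_true[j] / max(plaque_true[j], 1e-9))
                    nirs_bins[
                        _arc_mask(ca_center[j], 360 * frac, spec.n_bins)
                    ] |= int(Tissue.CA)
                if ca_cta[j] > 0:
                    frac = min(0.95, ca_cta[j] / max(plaque_cta[j], 1e-9))
                    cta_bins[
                        _arc_mask(ca_center[j], 360 * frac, spec.n_bins)
                    ] |= int(Tissue.CA)

                vessel_cta_j = lumen_cta[j] + plaque_cta[j]
                remaining = max(0.0, plaque_cta[j] - ca_cta[j])
                tissue_areas = {
                    "CA": float(ca_cta[j]),
                    "FT": float(0.6 * remaining),
                    "FF": float(0.25 * remaining),
                    "NC": float((0.12 if lipid_on[j] else 0.03) * remaining),
                }
                pairs.append(
                    (
                        Frame(
                            subject_id=subject,
                            vessel_id=vessel,
                            modality=Modality.NIRS_IVUS,
                            position=float(positions[j]),
                            lumen_area=float(lumen_nirs[j]),
                            vessel_area=float(lumen_nirs[j] + plaque_nirs[j]),
                            tissue_bins=nirs_bins,
                        ),
                        Frame(
                            subject_id=subject,
                            vessel_id=vessel,
                            modality=Modality.CTA,
                            position=float(positions[j]),
                            lumen_area=float(lumen_cta[j]),
                            vessel_area=float(vessel_cta_j),
                            tissue_bins=cta_bins,
                            tissue_areas=tissue_areas,
                        ),
                    )
                )
                truth_rows.append(
                    {
                        "subject_id": subject,
                        "vessel_id": vessel,
                        "position_mm": float(positions[j]),
                        "true_lumen_area_mm2": float(lumen_true[j]),
                        "true_plaque_area_mm2": float(plaque_true[j]),
                        "true_ca_area_mm2": float(ca_true[j]),
                    }
                )

    truth = {
        "spec": asdict(spec),
        "modality_intercepts": {"NIRS_IVUS": float(m_nirs), "CTA": float(m_cta)},
        "frames": pd.DataFrame(truth_rows),
    }
    return MatchedDataset(pairs), truth


# ---------------------------------------------------------------------------
# Focused simulators for the statistical components
# ---------------------------------------------------------------------------

def two_way_table(
    n_subjects: int,
    sigma_s: float,
    sigma_m: float,
    sigma_e: float,
    rng: np.random.Generator | int,
    mu: float = 0.0,
    random_modality: bool = False,
) -> pd.DataFrame:
    """Balanced two-way crossed random-effects data (2 modalities).

    ``value = mu + subject_effect + modality_effect + error`` with the
    stated standard deviations; the analytic ICC(A,2) is
    ``sigma_s^2 / (sigma_s^2 + (sigma_m^2 + sigma_e^2)/2)``.

    With only two modality levels the modality variance has a single
    degree of freedom, so a random draw makes the realised component (and
    hence the recoverable ICC) vary wildly between cohorts. By default the
    two effects are therefore set to ``+/- sigma_m / sqrt(2)``, whose
    sample variance is exactly ``sigma_m^2``, making the analytic ICC the
    recoverable per-cohort target; ``random_modality=True`` draws them
    instead.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    s = rng.normal(0, sigma_s, n_subjects)
    if random_modality:
        m = rng.normal(0, sigma_m, 2)
    else:
        m = np.array([1.0, -1.0]) * sigma_m / np.sqrt(2.0)
    e = rng.normal(0, sigma_e, (n_subjects, 2))
    vals = mu + s[:, None] + m[None, :] + e
    return pd.DataFrame(
        {
            "subject": np.repeat([f"S{i}" for i in range(n_subjects)], 2),
            "modality": np.tile(["NIRS_IVUS", "CTA"], n_subjects),
            "value": vals.ravel(),
        }
    )


def interaction_sample(
    n: int,
    gamma: float,
    rng: np.random.Generator | int,
    *,
    noise_sd: float = 1.0,
    ca_zero_prob: float = 0.4,
    ca_shape: float = 1.5,
    ca_scale: float = 2.0,
    n_subjects: int | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Paired measurements with a calcium x measurement interaction.

    ``nirs = cta + gamma * ca * cta + noise``: ``gamma = 0`` is the null
    of no calcium-dependent disagreement. The outcome is rounded to
    ``decimals`` decimals, mirroring the finite precision of reported
    measurements (and bounding the ordinal category count of the
    proportional-odds fit); predictors stay at full precision.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    cta = rng.lognormal(1.2, 0.5, n)
    ca = np.where(
        rng.random(n) < ca_zero_prob, 0.0, rng.gamma(ca_shape, ca_scale, n)
    )
    nirs = cta + gamma * ca * cta + rng.normal(0, noise_sd, n)
    subj = (
        rng.integers(0, n_subjects, n)
        if n_subjects is not None
        else np.arange(n)
    )
    return pd.DataFrame(
        {
            "nirs": np.round(nirs, decimals),
            "cta": cta,
            "ca": ca,
            "subject": subj,
        }
    )
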