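"""Synthetic TD-fNIRS cohorts with programmable group structure.

The generator emulates a two-group (healthy control vs. depression),
two-session verbal-fluency block design on a 22-channel prefrontal probe.
Each channel carries either an *activated* response (oxyhemoglobin rising
above its rest level after task onset and relaxing back afterwards) or a
*suppressive* response (oxyhemoglobin dipping below rest during the task).
Group differences are programmed per delay-pair family and per response
class as amplitude / onset-latency / time-to-peak offsets, with lognormal
between-subject amplitude variability and Gaussian timing variability.

Two rendering modes:

* ``hbo_direct`` - the task/rest ratio series are emitted directly (fast;
  used for statistical calibration studies);
* ``tpsf`` - full photon time-of-flight histograms are synthesized per
  channel and wavelength as Poisson draws around the semi-infinite
  diffusion-model reflectance, driven by the programmed hemoglobin
  trajectory through the extinction table (used to validate the physics
  inversions end to end).

A configurable fraction of channels is corrupted with one of three
artifact archetypes (dead channel, drifting gain, burst outliers) to
exercise channel rejection.  Seeding is counter-based per subject and
session, so enlarging a cohort never reshuffles existing subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .physics import (
    DEFAULT_GATE_SET,
    RHBO,
    ExtinctionTable,
    GateSet,
    HbOSeries,
    OpticalProperties,
    TPSFRecord,
    _reflectance_raw,
)
from .protocol import TaskProtocol

ACTIVATED = "activated"
SUPPRESSIVE = "suppressive"
FAMILIES = ("RHbO1", "RHbO2")
ARTIFACTS = ("dead", "drift", "burst")
GROUPS = ("HC", "MDD")


# ---------------------------------------------------------------------------
# effect specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseClassParams:
    """Mean response-curve parameters for one class (ratio scale)."""

    amplitude: float  # peak |RHbO - 1|
    latency_s: float  # onset delay after task start
    time_to_peak_s: float  # peak time after onset

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.time_to_peak_s <= 0:
            raise ValueError("time_to_peak_s must be positive")


@dataclass(frozen=True)
class FamilyEffect:
    activated: ResponseClassParams
    suppressive: ResponseClassParams
    suppressive_fraction: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.suppressive_fraction <= 1.0:
            raise ValueError("suppressive_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GroupEffect:
    rhbo1: FamilyEffect
    rhbo2: FamilyEffect

    def family(self, name: str) -> FamilyEffect:
        return {"RHbO1": self.rhbo1, "RHbO2": self.rhbo2}[name]


@dataclass(frozen=True)
class VariabilitySpec:
    """Between-subject and within-recording variability (session effect 0)."""

    amplitude_rel_sd: float = 0.35  # lognormal sigma on amplitudes
    latency_sd_s: float = 3.0
    time_to_peak_sd_s: float = 4.0
    channel_amplitude_rel_sd: float = 0.20
    channel_latency_sd_s: float = 1.0
    session_shift: float = 0.0  # fractional amplitude shift in session 2


@dataclass(frozen=True)
class GroupEffectSpec:
    hc: GroupEffect
    mdd: GroupEffect
    variability: VariabilitySpec = VariabilitySpec()

    def group(self, name: str) -> GroupEffect:
        return {"HC": self.hc, "MDD": self.mdd}[name]


def default_effects() -> GroupEffectSpec:
    """Defaults encoding the depression-group effect directions.

    Relative to controls the depression group carries: a stronger
    suppressive response in the early delay-pair family (larger |integral
    of suppression|), a stronger and earlier activated response in the late
    delay-pair family (larger activation integral, earlier activation
    centroid), and earlier channel-average timing in both families.
    """
    hc = GroupEffect(
        rhbo1=FamilyEffect(
            activated=ResponseClassParams(0.030, 10.0, 24.0),
            suppressive=ResponseClassParams(0.020, 8.0, 22.0),
            suppressive_fraction=0.40,
        ),
        rhbo2=FamilyEffect(
            activated=ResponseClassParams(0.040, 12.0, 25.0),
            suppressive=ResponseClassParams(0.025, 8.0, 22.0),
            suppressive_fraction=0.40,
        ),
    )
    mdd = GroupEffect(
        rhbo1=FamilyEffect(
            activated=ResponseClassParams(0.030, 7.0, 22.0),
            suppressive=ResponseClassParams(0.032, 6.0, 20.0),
            suppressive_fraction=0.45,
        ),
        rhbo2=FamilyEffect(
            activated=ResponseClassParams(0.058, 9.5, 22.5),
            suppressive=ResponseClassParams(0.025, 8.0, 22.0),
            suppressive_fraction=0.40,
        ),
    )
    return GroupEffectSpec(hc=hc, mdd=mdd)


def null_effects() -> GroupEffectSpec:
    """Both groups share the control parameters (no programmed effect)."""
    base = default_effects()
    return GroupEffectSpec(hc=base.hc, mdd=base.hc, variability=base.variability)


# ---------------------------------------------------------------------------
# response curve
# ---------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _shape_peak(shape: float, undershoot: float, k_under: float) -> tuple[float, float]:
    """Location and value of the maximum of the unit-free curve F(x)."""
    x = np.linspace(1e-4, 4.0, 8001)
    f = _shape_fn(x, shape, undershoot, k_under)
    i = int(np.argmax(f))
    return float(x[i]), float(f[i])


def _shape_fn(x: np.ndarray, shape: float, undershoot: float, k_under: float) -> np.ndarray:
    main = np.where(x > 0, np.power(np.maximum(x, 0), shape) * np.exp(shape * (1.0 - x)), 0.0)
    xu = x / k_under
    under = np.where(x > 0, np.power(np.maximum(xu, 0), shape) * np.exp(shape * (1.0 - xu)), 0.0)
    return main - undershoot * under


def _unit_curves(
    latency_s: np.ndarray,
    time_to_peak_s: np.ndarray,
    protocol: TaskProtocol,
    shape: float = 3.0,
    undershoot: float = 0.12,
    k_under: float = 2.2,
) -> np.ndarray:
    """Unit-peak response curves, one row per (latency, time-to-peak) pair.

    The curve is a difference of two gamma-variate bumps rescaled so the
    maximum equals 1 exactly at ``onset + latency + time_to_peak``.
    """
    xpeak, fpeak = _shape_peak(shape, undershoot, k_under)
    t = protocol.frame_times_s
    u = t[np.newaxis, :] - (protocol.task_onset_s + np.atleast_1d(latency_s)[:, np.newaxis])
    x = xpeak * u / np.atleast_1d(time_to_peak_s)[:, np.newaxis]
    return _shape_fn(x, shape, undershoot, k_under) / fpeak


def hrf_curve(
    kind: str,
    params: ResponseClassParams,
    protocol: TaskProtocol,
    shape: float = 3.0,
    undershoot: float = 0.12,
    reference: float = 1.0,
) -> np.ndarray:
    """Deterministic single-channel response curve on the protocol grid.

    Activated curves rise above ``reference`` after ``task onset +
    latency`` and relax back toward baseline post-task; suppressive curves
    mirror below the reference.  The value before onset is exactly the
    reference and the peak deviation equals ``params.amplitude``.
    """
    if kind not in (ACTIVATED, SUPPRESSIVE):
        raise ValueError(f"kind must be {ACTIVATED!r} or {SUPPRESSIVE!r}")
    if params.latency_s >= protocol.task_s:
        raise ValueError("latency must be shorter than the task block")
    unit = _unit_curves(
        np.array([params.latency_s]),
        np.array([params.time_to_peak_s]),
        protocol,
        shape,
        undershoot,
    )[0]
    sign = 1.0 if kind == ACTIVATED else -1.0
    return reference + sign * params.amplitude * unit


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Study-design parameters of one synthetic cohort.

    Defaults mirror the target study design: 27 subjects per group, two
    sessions each (108 recordings), 22 channels with a 0.34 per-channel
    corruption probability, and a 30/60/70 s rest-task-rest block at 1 Hz.
    """

    n_per_group: int = 27
    sessions_per_subject: int = 2
    n_channels: int = 22
    corruption_probability: float = 0.34
    photon_budget: float = 1e6  # expected counts per frame per channel/wavelength
    seed: int = 0
    effects: GroupEffectSpec = field(default_factory=default_effects)
    protocol: TaskProtocol = field(default_factory=TaskProtocol)
    mode: str = "hbo_direct"  # or "tpsf"
    noise_sd: float = 0.010  # white noise on the ratio scale
    poisson_noise: bool = True  # photon noise in tpsf mode
    baseline_hbo_um: float = 60.0
    baseline_hbr_um: float = 25.0
    hbr_coupling: float = 0.25  # dHbR = -coupling * dHbO
    optical: OpticalProperties = field(
        default_factory=lambda: OpticalProperties(mua=0.01, musp=1.0, n_tissue=1.4, rho=30.0)
    )
    gate_set: GateSet = field(default_factory=lambda: DEFAULT_GATE_SET)
    extinction: ExtinctionTable = field(default_factory=ExtinctionTable.default)
    tpsf_bin_width_ps: float = 50.0
    tpsf_max_ps: float = 4000.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 <= self.corruption_probability < 1.0:
            raise ValueError("corruption_probability must be in [0, 1)")
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")
        if self.mode not in ("hbo_direct", "tpsf"):
            raise ValueError("mode must be 'hbo_direct' or 'tpsf'")


@dataclass
class SyntheticSample:
    sample_id: str
    subject_id: str
    group: str
    session: int
    hbo: dict[str, HbOSeries] | None = None
    tpsf: list[TPSFRecord] | None = None


@dataclass
class Cohort:
    spec: CohortSpec
    samples: list[SyntheticSample]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# parameter drawing (counter-based seeding)
# ---------------------------------------------------------------------------


@dataclass
class _SampleParams:
    """Ground-truth per-channel parameters for one recording."""

    # per family: dict with arrays over channels
    kinds: dict[str, np.ndarray]  # bool, True = suppressive
    amplitudes: dict[str, np.ndarray]
    latencies: dict[str, np.ndarray]
    ttps: dict[str, np.ndarray]
    corrupted: np.ndarray  # bool per channel
    artifact: np.ndarray  # int index into ARTIFACTS
    noise_seed: np.random.SeedSequence


def _subject_rng(spec: CohortSpec, group_idx: int, subj_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(group_idx, subj_idx))
    )


def _draw_sample_params(
    spec: CohortSpec, group: str, subj_idx: int, session: int
) -> _SampleParams:
    g_idx = GROUPS.index(group)
    var = spec.effects.variability
    rng_subj = _subject_rng(spec, g_idx, subj_idx)
    task_s = spec.protocol.task_s

    # subject-level means per family/class; identical across sessions
    subj: dict[tuple[str, str], tuple[float, float, float]] = {}
    for fam in FAMILIES:
        eff = spec.effects.group(group).family(fam)
        for klass, p in ((ACTIVATED, eff.activated), (SUPPRESSIVE, eff.suppressive)):
            s = var.amplitude_rel_sd
            amp = p.amplitude * np.exp(s * rng_subj.standard_normal() - 0.5 * s * s)
            lat = np.clip(
                rng_subj.normal(p.latency_s, var.latency_sd_s), 0.0, 0.8 * task_s
            )
            ttp = np.clip(
                rng_subj.normal(p.time_to_peak_s, var.time_to_peak_sd_s), 3.0, task_s
            )
            subj[(fam, klass)] = (float(amp), float(lat), float(ttp))

    sess_key = (g_idx, subj_idx, session, 1)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=sess_key))
    n_ch = spec.n_channels
    shift = 1.0 + var.session_shift if session == 2 else 1.0

    kinds, amps, lats, ttps = {}, {}, {}, {}
    for fam in FAMILIES:
        eff = spec.effects.group(group).family(fam)
        sup = rng.random(n_ch) < eff.suppressive_fraction
        kinds[fam] = sup
        a = np.empty(n_ch)
        l = np.empty(n_ch)
        tt = np.empty(n_ch)
        for klass, mask in ((ACTIVATED, ~sup), (SUPPRESSIVE, sup)):
            amp0, lat0, ttp0 = subj[(fam, klass)]
            s = var.channel_amplitude_rel_sd
            jit = np.exp(s * rng.standard_normal(n_ch) - 0.5 * s * s)
            a[mask] = (amp0 * shift) * jit[mask]
            l[mask] = np.clip(
                lat0 + rng.normal(0.0, var.channel_latency_sd_s, n_ch)[mask],
                0.0,
                0.9 * task_s,
            )
            tt[mask] = ttp0
        amps[fam], lats[fam], ttps[fam] = a, l, tt

    corrupted = rng.random(n_ch) < spec.corruption_probability
    artifact = rng.integers(0, len(ARTIFACTS), n_ch)
    noise_seed = np.random.SeedSequence(spec.seed, spawn_key=(g_idx, subj_idx, session, 2))
    return _SampleParams(kinds, amps, lats, ttps, corrupted, artifact, noise_seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _ratio_curves(params: _SampleParams, fam: str, protocol: TaskProtocol) -> np.ndarray:
    unit = _unit_curves(params.latencies[fam], params.ttps[fam], protocol)
    sign = np.where(params.kinds[fam], -1.0, 1.0)
    return 1.0 + sign[:, np.newaxis] * params.amplitudes[fam][:, np.newaxis] * unit


def _corrupt_ratio(values: np.ndarray, params: _SampleParams, rng: np.random.Generator) -> None:
    """Apply artifact archetypes in place on ratio-scale series."""
    n_frames = values.shape[1]
    ramp = np.arange(n_frames) / max(n_frames - 1, 1)
    for ch in np.flatnonzero(params.corrupted):
        kind = ARTIFACTS[params.artifact[ch]]
        if kind == "dead":
            values[ch] = rng.normal(0.0, 0.005, n_frames)
        elif kind == "drift":
            delta = rng.uniform(0.3, 0.5) * rng.choice([-1.0, 1.0])
            values[ch] = values[ch] * (1.0 + delta * ramp)
        else:  # burst
            n_spk = max(1, int(0.08 * n_frames))
            idx = rng.choice(n_frames, n_spk, replace=False)
            values[ch, idx] += rng.choice([-1.0, 1.0], n_spk) * rng.uniform(0.15, 0.35, n_spk)


def _render_direct(spec: CohortSpec, params: _SampleParams) -> dict[str, HbOSeries]:
    rng = np.random.default_rng(params.noise_seed)
    out: dict[str, HbOSeries] = {}
    for pair_idx, fam in enumerate(FAMILIES, start=1):
        vals = _ratio_curves(params, fam, spec.protocol)
        vals = vals + rng.normal(0.0, spec.noise_sd, vals.shape)
        _corrupt_ratio(vals, params, rng)
        out[fam] = HbOSeries(
            kind=RHBO,
            index=pair_idx,
            values=vals,
            frame_times_s=spec.protocol.frame_times_s,
            channel_ids=tuple(range(1, spec.n_channels + 1)),
            protocol=spec.protocol,
        )
    return out


def _render_tpsf(spec: CohortSpec, params: _SampleParams) -> list[TPSFRecord]:
    """Photon-count histograms driven by the late-pair family trajectory.

    A single physical hemoglobin trajectory underlies both wavelengths and
    all delay gates, so in this mode the programmed structure of the
    ``RHbO2`` family defines the physiology; the early/late delay pairs
    then probe the same trajectory through the diffusion model.
    """
    rng = np.random.default_rng(params.noise_seed)
    protocol = spec.protocol
    ratio = _ratio_curves(params, "RHbO2", protocol)
    ratio = ratio + rng.normal(0.0, spec.noise_sd, ratio.shape)

    hbo = spec.baseline_hbo_um * ratio  # (ch, T)
    hbr = spec.baseline_hbr_um - spec.hbr_coupling * (hbo - spec.baseline_hbo_um)
    hbr = np.maximum(hbr, 1.0)

    wavelengths = spec.extinction.wavelengths_nm
    e = spec.extinction.matrix(tuple(wavelengths))
    conc = np.stack([hbo, hbr], axis=1)  # (ch, 2, T)
    mua = np.einsum("ij,cjt->cit", e, conc)  # (ch, wl, T)
    mua0 = e @ np.array([spec.baseline_hbo_um, spec.baseline_hbr_um])

    edges = np.arange(0.0, spec.tpsf_max_ps + spec.tpsf_bin_width_ps, spec.tpsf_bin_width_ps)
    centers = 0.5 * (edges[:-1] + edges[1:])
    opt = spec.optical
    m = _reflectance_raw(centers, 0.0, opt.musp, opt.n_tissue, opt.rho, "extrapolated")
    v = opt.v_mm_per_ps

    # photon-budget feasibility: expected baseline counts in the last gate
    last_gate = spec.gate_set.gates[-1]
    gmask = (centers >= last_gate[0]) & (centers < last_gate[1])
    base_shape = m * np.exp(-float(np.max(mua0)) * v * centers)
    frac_last = base_shape[gmask].sum() / base_shape.sum()
    if spec.photon_budget * frac_last < 1.0:
        warnings.warn(
            f"photon budget {spec.photon_budget:g} yields expected counts "
            f"{spec.photon_budget * frac_last:.2g} (<1) in the latest gate",
            stacklevel=2,
        )

    frame_times = protocol.frame_times_s
    ramp = np.arange(len(frame_times)) / max(len(frame_times) - 1, 1)
    records: list[TPSFRecord] = []
    for ch in range(spec.n_channels):
        for w, wl in enumerate(wavelengths):
            shape0 = m * np.exp(-mua0[w] * v * centers)
            scale = spec.photon_budget / shape0.sum()
            lam = scale * m[np.newaxis, :] * np.exp(-np.outer(mua[ch, w], v * centers))
            if params.corrupted[ch]:
                kind = ARTIFACTS[params.artifact[ch]]
                if kind == "dead":
                    lam = lam * 1e-5
                elif kind == "drift":
                    delta = rng.uniform(0.3, 0.5) * rng.choice([-1.0, 1.0])
                    lam = lam * (1.0 + delta * ramp)[:, np.newaxis]
                else:
                    n_spk = max(1, int(0.08 * len(frame_times)))
                    idx = rng.choice(len(frame_times), n_spk, replace=False)
                    lam[idx] *= 8.0
            counts = rng.poisson(lam).astype(float) if spec.poisson_noise else lam
            records.append(
                TPSFRecord(
                    channel_id=ch + 1,
                    wavelength_nm=wl,
                    bin_edges_ps=edges,
                    counts=counts,
                    frame_times_s=frame_times,
                )
            )
    return records


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a reproducible cohort plus its ground-truth table.

    The truth table holds one row per (sample, family, channel) with the
    programmed response class, curve parameters and corruption state -
    enough to score channel rejection, response classification and the
    downstream feature statistics against the generating process.
    """
    samples: list[SyntheticSample] = []
    rows: list[dict] = []
    for g_idx, group in enumerate(GROUPS):
        for subj_idx in range(spec.n_per_group):
            subject_id = f"{group}{subj_idx + 1:03d}"
            for session in range(1, spec.sessions_per_subject + 1):
                params = _draw_sample_params(spec, group, subj_idx, session)
                sample_id = f"{subject_id}_s{session}"
                sample = SyntheticSample(
                    sample_id=sample_id, subject_id=subject_id, group=group, session=session
                )
                if spec.mode == "hbo_direct":
                    sample.hbo = _render_direct(spec, params)
                else:
                    sample.tpsf = _render_tpsf(spec, params)
                samples.append(sample)
                for fam in FAMILIES:
                    for ch in range(spec.n_channels):
                        rows.append(
                            {
                                "sample_id": sample_id,
                                "subject_id": subject_id,
                                "group": group,
                                "session": session,
                                "family": fam,
                                "channel": ch + 1,
                                "response_class": SUPPRESSIVE
                                if params.kinds[fam][ch]
                                else ACTIVATED,
                                "corrupted": bool(params.corrupted[ch]),
                                "artifact": ARTIFACTS[params.artifact[ch]]
                                if params.corrupted[ch]
                                else "",
                                "amplitude": params.amplitudes[fam][ch],
                                "latency_s": params.latencies[fam][ch],
                                "time_to_peak_s": params.ttps[fam][ch],
                            }
                        )
    return Cohort(spec=spec, samples=samples, truth=pd.DataFrame(rows))
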