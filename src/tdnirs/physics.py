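"""Time-resolved diffuse optics: forward model and inverse hemodynamics.

This module implements the photon-migration layer of the pipeline:

* the closed-form time-resolved diffuse reflectance ``R(rho, t)`` of a
  semi-infinite homogeneous medium (diffusion-equation solution with either
  an extrapolated or a zero boundary condition);
* delay gating of temporal point spread functions (TPSFs) into a small set
  of intensity channels;
* the modified Beer-Lambert law (MBLL) giving per-gate oxyhemoglobin
  changes ``dHbO_i`` in uM;
* absorption-coefficient estimation from a *pair* of delay gates, and from
  it the task-rest oxyhemoglobin ratio ``RHbO_i`` (dimensionless).

Conventions: distances in mm, times in ps (frame times in s), absorption
and reduced scattering coefficients in 1/mm, concentrations in uM,
extinction coefficients in 1/(mm*uM).  The diffusion coefficient is taken
as ``D = 1/(3*musp)`` so that absorption factorizes out of the solution as
``exp(-mua*v*t)``; this factorization is what makes the two-gate slope
inversion exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .protocol import TaskProtocol

#: speed of light in vacuum, mm/ps
C_MM_PER_PS = 0.299792458

DELTA_HBO = "delta_hbo"
RHBO = "rhbo"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of the probed tissue and probe geometry.

    mua : absorption coefficient (1/mm); musp : reduced scattering
    coefficient (1/mm); n_tissue : refractive index; rho : source-detector
    separation (mm).  Scattering and geometry are treated as fixed within a
    recording; only absorption follows the hemodynamics.
    """

    mua: float
    musp: float
    n_tissue: float = 1.4
    rho: float = 30.0

    def __post_init__(self) -> None:
        if self.mua <= 0 or self.musp <= 0 or self.rho <= 0:
            raise ValueError("mua, musp and rho must be positive")
        if self.n_tissue < 1.0:
            raise ValueError("n_tissue must be >= 1")

    @property
    def v_mm_per_ps(self) -> float:
        return C_MM_PER_PS / self.n_tissue


@dataclass(frozen=True)
class GateSet:
    """Three ordered, disjoint delay windows over the TPSF, in ps.

    Gate index ``i`` (1-based) corresponds to the delay index of
    ``dHbO_i``; the delay *pair* index of ``RHbO_i`` refers to gates
    ``(i, i+1)``.
    """

    gates: tuple[tuple[float, float], ...] = ((500.0, 1000.0), (1500.0, 2000.0), (2500.0, 3000.0))

    def __post_init__(self) -> None:
        if len(self.gates) != 3:
            raise ValueError("a GateSet holds exactly 3 delay gates")
        prev_end = -np.inf
        for start, end in self.gates:
            if not start < end:
                raise ValueError(f"gate ({start}, {end}) must have start < end")
            if start < prev_end:
                raise ValueError("gates must be ordered and disjoint")
            prev_end = end

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(range(1, len(self.gates) + 1))

    @property
    def centers_ps(self) -> np.ndarray:
        return np.array([(a + b) / 2.0 for a, b in self.gates])

    @property
    def widths_ps(self) -> np.ndarray:
        return np.array([b - a for a, b in self.gates])

    def pair(self, index: int) -> tuple[int, int]:
        """0-based gate indices for delay-pair ``index`` (1 or 2)."""
        if index not in (1, 2):
            raise ValueError("delay pair index must be 1 (gates 1-2) or 2 (gates 2-3)")
        return index - 1, index


DEFAULT_GATE_SET = GateSet()


@dataclass
class TPSFRecord:
    """One channel/wavelength photon time-of-flight histogram over frames.

    ``counts`` has shape (n_frames, n_bins); noise-free synthetic records
    may carry expected (non-integer) counts.
    """

    channel_id: int
    wavelength_nm: float
    bin_edges_ps: np.ndarray
    counts: np.ndarray
    frame_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges_ps = np.asarray(self.bin_edges_ps, float)
        self.counts = np.asarray(self.counts, float)
        self.frame_times_s = np.asarray(self.frame_times_s, float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (frames, bins)")
        if len(self.bin_edges_ps) != self.counts.shape[1] + 1:
            raise ValueError("len(bin_edges_ps) must equal n_bins + 1")
        if np.any(np.diff(self.bin_edges_ps) <= 0):
            raise ValueError("bin_edges_ps must be strictly increasing")
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame_times_s must be strictly increasing")
        if len(self.frame_times_s) != self.counts.shape[0]:
            raise ValueError("frame_times_s length must match counts")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def bin_centers_ps(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ps[:-1] + self.bin_edges_ps[1:])


@dataclass
class GatedSeries:
    """Gated intensities, shape (n_channels, n_wavelengths, n_gates, n_frames)."""

    values: np.ndarray
    channel_ids: tuple[int, ...]
    wavelengths_nm: tuple[float, ...]
    gate_set: GateSet
    frame_times_s: np.ndarray
    protocol: TaskProtocol | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.frame_times_s = np.asarray(self.frame_times_s, float)
        expected = (
            len(self.channel_ids),
            len(self.wavelengths_nm),
            len(self.gate_set.gates),
            len(self.frame_times_s),
        )
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise ValueError("gated intensities must be nonnegative")


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of HbO2 and HHb, in 1/(mm*uM).

    Shipped defaults are the widely used base-10 compilation values for
    760/850 nm converted to natural-log, per-mm, per-uM units.
    """

    wavelengths_nm: tuple[float, ...]
    eps_hbo: tuple[float, ...]
    eps_hbr: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.wavelengths_nm) == len(self.eps_hbo) == len(self.eps_hbr)):
            raise ValueError("column lengths must agree")
        if any(e <= 0 for e in self.eps_hbo) or any(e <= 0 for e in self.eps_hbr):
            raise ValueError("extinction coefficients must be positive")

    @classmethod
    def default(cls) -> "ExtinctionTable":
        # base-10 molar coefficients 586/1548.52 (760 nm) and 1058/691.32
        # (850 nm) in 1/(cm*M), times ln(10)*1e-7 to get 1/(mm*uM)
        f = float(np.log(10.0)) * 1e-7
        return cls(
            wavelengths_nm=(760.0, 850.0),
            eps_hbo=(float(586.0 * f), float(1058.0 * f)),
            eps_hbr=(float(1548.52 * f), float(691.32 * f)),
        )

    def matrix(self, wavelengths: tuple[float, float]) -> np.ndarray:
        """2x2 system matrix rows=[wavelength], cols=[HbO, HbR]."""
        rows = []
        for wl in wavelengths:
            try:
                i = self.wavelengths_nm.index(wl)
            except ValueError as exc:
                raise KeyError(f"wavelength {wl} nm not in extinction table") from exc
            rows.append([self.eps_hbo[i], self.eps_hbr[i]])
        e = np.array(rows)
        if np.linalg.cond(e) > 1e8:
            raise ValueError("extinction matrix is singular for this wavelength pair")
        return e


@dataclass
class HbOSeries:
    """Per-channel oxyhemoglobin time series.

    ``kind`` is ``"delta_hbo"`` (uM, per delay gate ``index`` 1-3) or
    ``"rhbo"`` (dimensionless task/rest ratio, per delay pair ``index``
    1-2).  Channels flagged unusable during derivation are listed in
    ``bad_channels`` and carry NaN values.
    """

    kind: str
    index: int
    values: np.ndarray
    frame_times_s: np.ndarray
    channel_ids: tuple[int, ...]
    protocol: TaskProtocol | None = None
    bad_channels: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in (DELTA_HBO, RHBO):
            raise ValueError(f"unknown series kind {self.kind!r}")
        self.values = np.asarray(self.values, float)
        self.frame_times_s = np.asarray(self.frame_times_s, float)
        if self.values.shape != (len(self.channel_ids), len(self.frame_times_s)):
            raise ValueError("values must be (n_channels, n_frames)")

    @property
    def reference(self) -> float:
        """Rest-state reference level: 1 for a ratio, 0 for a change."""
        return 1.0 if self.kind == RHBO else 0.0


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _boundary_coefficient(n_tissue: float) -> float:
    """Internal-reflection factor A for the extrapolated boundary."""
    n = n_tissue
    r_eff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_eff) / (1.0 - r_eff)


def _reflectance_raw(
    t_ps: np.ndarray,
    mua: float,
    musp: float,
    n_tissue: float,
    rho: float,
    boundary: str,
) -> np.ndarray:
    """R(rho, t) without argument validation; accepts mua = 0."""
    t = np.asarray(t_ps, float)
    v = C_MM_PER_PS / n_tissue
    d = 1.0 / (3.0 * musp)
    z0 = 1.0 / musp
    four_dvt = 4.0 * d * v * t
    pref = (4.0 * np.pi * d * v) ** -1.5 * t**-2.5
    atten = np.exp(-mua * v * t - rho**2 / four_dvt)
    if boundary == "zero":
        return pref * z0 * np.exp(-(z0**2) / four_dvt) * atten
    if boundary == "extrapolated":
        zb = 2.0 * _boundary_coefficient(n_tissue) * d
        z1 = z0 + 2.0 * zb
        return (
            0.5
            * pref
            * atten
            * (z0 * np.exp(-(z0**2) / four_dvt) + z1 * np.exp(-(z1**2) / four_dvt))
        )
    raise ValueError("boundary must be 'extrapolated' or 'zero'")


def semi_infinite_reflectance(
    t_ps: np.ndarray | float,
    props: OpticalProperties,
    boundary: str = "extrapolated",
) -> np.ndarray:
    """Time-resolved diffuse reflectance of a semi-infinite medium.

    Returns the closed-form diffusion-equation reflectance at
    source-detector separation ``props.rho`` (arbitrary units,
    photons/mm^2/ps up to a source scale).  Strictly positive, and strictly
    decreasing in ``props.mua`` at fixed ``t``.
    """
    t = np.asarray(t_ps, float)
    if np.any(t <= 0):
        raise ValueError("t_ps must be positive")
    return _reflectance_raw(t, props.mua, props.musp, props.n_tissue, props.rho, boundary)


def reflectance_mua_free(
    t_ps: np.ndarray | float, props: OpticalProperties, boundary: str = "extrapolated"
) -> np.ndarray:
    """The absorption-independent factor M(t) of the DE solution."""
    t = np.asarray(t_ps, float)
    if np.any(t <= 0):
        raise ValueError("t_ps must be positive")
    return _reflectance_raw(t, 0.0, props.musp, props.n_tissue, props.rho, boundary)


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------


def _gate_counts(record: TPSFRecord, gate_set: GateSet) -> np.ndarray:
    """Sum counts over whole bins whose centers fall inside each gate."""
    lo, hi = record.bin_edges_ps[0], record.bin_edges_ps[-1]
    centers = record.bin_centers_ps
    out = np.empty((len(gate_set.gates), record.counts.shape[0]))
    for g, (start, end) in enumerate(gate_set.gates):
        if start < lo or end > hi:
            raise ValueError(
                f"gate ({start}, {end}) ps outside TPSF support [{lo}, {hi}] ps"
            )
        mask = (centers >= start) & (centers < end)
        out[g] = record.counts[:, mask].sum(axis=1)
    return out


def gate_tpsf(record: TPSFRecord, gate_set: GateSet = DEFAULT_GATE_SET) -> GatedSeries:
    """Gate a single TPSF record into per-delay intensities."""
    vals = _gate_counts(record, gate_set)[np.newaxis, np.newaxis]
    return GatedSeries(
        values=vals,
        channel_ids=(record.channel_id,),
        wavelengths_nm=(record.wavelength_nm,),
        gate_set=gate_set,
        frame_times_s=record.frame_times_s,
    )


def gate_records(
    records: list[TPSFRecord],
    gate_set: GateSet = DEFAULT_GATE_SET,
    protocol: TaskProtocol | None = None,
) -> GatedSeries:
    """Gate a full multichannel, two-wavelength recording."""
    if not records:
        raise ValueError("no TPSF records supplied")
    channel_ids = tuple(sorted({r.channel_id for r in records}))
    wavelengths = tuple(sorted({r.wavelength_nm for r in records}))
    frame_times = records[0].frame_times_s
    n_frames = len(frame_times)
    vals = np.full((len(channel_ids), len(wavelengths), len(gate_set.gates), n_frames), np.nan)
    for rec in records:
        if not np.allclose(rec.frame_times_s, frame_times):
            raise ValueError("all records must share one frame-time grid")
        c = channel_ids.index(rec.channel_id)
        w = wavelengths.index(rec.wavelength_nm)
        vals[c, w] = _gate_counts(rec, gate_set)
    if np.any(np.isnan(vals)):
        raise ValueError("missing (channel, wavelength) combinations in records")
    return GatedSeries(
        values=vals,
        channel_ids=channel_ids,
        wavelengths_nm=wavelengths,
        gate_set=gate_set,
        frame_times_s=frame_times,
        protocol=protocol,
    )


# ---------------------------------------------------------------------------
# MBLL inversion (per-gate dHbO)
# ---------------------------------------------------------------------------


def pathlengths_from_gates(gate_set: GateSet, n_tissue: float = 1.4) -> np.ndarray:
    """Effective pathlength per gate, L_i = v * t_center (mm).

    In a time-domain measurement the photon pathlength is proportional to
    the arrival time, so each delay gate carries its own effective
    pathlength rather than a single DPF.
    """
    v = C_MM_PER_PS / n_tissue
    return v * gate_set.centers_ps


def mbll_delta_hbo(
    gated: GatedSeries,
    baseline_window: tuple[float, float],
    ext: ExtinctionTable | None = None,
    pathlengths_mm: np.ndarray | None = None,
    n_tissue: float = 1.4,
    protocol: TaskProtocol | None = None,
) -> list[HbOSeries]:
    """Per-delay oxyhemoglobin changes via the modified Beer-Lambert law.

    For each gate ``i``, channel and wavelength the optical-density change
    is ``dOD = -ln(I_i(t) / <I_i>_baseline)``; the 2x2 extinction system
    ``dOD = L_i * E @ [dHbO, dHbR]`` is solved and the dHbO component
    returned as one series per delay gate.  Channels with nonpositive
    baseline intensity are flagged unusable (NaN).
    """
    ext = ext or ExtinctionTable.default()
    if len(gated.wavelengths_nm) != 2:
        raise ValueError("MBLL inversion requires exactly two wavelengths")
    if pathlengths_mm is None:
        pathlengths_mm = pathlengths_from_gates(gated.gate_set, n_tissue)
    pathlengths_mm = np.asarray(pathlengths_mm, float)
    e_inv = np.linalg.inv(ext.matrix(tuple(gated.wavelengths_nm)))

    w0, w1 = baseline_window
    base = (gated.frame_times_s >= w0) & (gated.frame_times_s < w1)
    if not np.any(base):
        raise ValueError("baseline window contains no frames")

    intens = gated.values  # (ch, wl, gate, T)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base_mean = np.nanmean(np.where(intens[..., base] > 0, intens[..., base], np.nan), axis=-1)
    bad = ~np.all(np.isfinite(base_mean) & (base_mean > 0), axis=(1, 2))

    out: list[HbOSeries] = []
    for g, label in enumerate(gated.gate_set.labels):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = intens[:, :, g, :] / base_mean[:, :, g, np.newaxis]
            dod = -np.log(np.where(ratio > 0, ratio, np.nan))
        conc = np.einsum("ij,cjt->cit", e_inv, dod) / pathlengths_mm[g]
        hbo = conc[:, 0, :]
        hbo[bad] = np.nan
        out.append(
            HbOSeries(
                kind=DELTA_HBO,
                index=label,
                values=hbo,
                frame_times_s=gated.frame_times_s,
                channel_ids=gated.channel_ids,
                protocol=protocol or gated.protocol,
                bad_channels=frozenset(np.array(gated.channel_ids)[bad].tolist()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# delay-pair absorption estimate and RHbO
# ---------------------------------------------------------------------------


@dataclass
class MuaEstimate:
    """Absorption estimates per (channel, wavelength, frame), 1/mm."""

    values: np.ndarray
    pair: int
    wavelengths_nm: tuple[float, ...]
    channel_ids: tuple[int, ...]
    frame_times_s: np.ndarray
    n_floored: int = 0
    n_missing: int = 0


@lru_cache(maxsize=32)
def _pair_inversion_table(
    gate_a: tuple[float, float],
    gate_b: tuple[float, float],
    musp: float,
    n_tissue: float,
    rho: float,
    boundary: str,
    mua_max: float,
    n_grid: int,
    n_quad: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Monotone lookup mua -> gate log-intensity ratio ln(I_a/I_b).

    The forward gated intensity is the gate integral of
    ``M(t) exp(-mua*v*t)``; the log ratio between the two gates of a pair
    is strictly increasing in mua, so its tabulation inverts exactly.
    """
    v = C_MM_PER_PS / n_tissue
    mu = np.linspace(0.0, mua_max, n_grid)
    q = []
    for gate in (gate_a, gate_b):
        t = np.linspace(gate[0], gate[1], n_quad)
        m = _reflectance_raw(t, 0.0, musp, n_tissue, rho, boundary)
        integ = np.trapezoid(m[np.newaxis, :] * np.exp(-np.outer(mu, v * t)), t, axis=1)
        q.append(np.log(integ))
    log_ratio = q[0] - q[1]
    return mu, log_ratio


def estimate_mua_from_pair(
    gated: GatedSeries,
    pair: int,
    props_prior: OpticalProperties,
    boundary: str = "extrapolated",
    method: str = "interp",
    mua_floor: float = 1e-4,
    mua_max: float = 0.1,
) -> MuaEstimate:
    """Estimate mua per channel/wavelength/frame from one delay pair.

    ``method="interp"`` (default) inverts the gate-integrated forward model
    through a monotone lookup table; ``method="midpoint"`` uses the closed
    form ``mua = [ln(I_a/I_b) - ln(M(ta)/M(tb))] / (v*(tb - ta))`` with M
    evaluated at the gate-center times.  Frames with nonpositive intensity
    at either gate are flagged missing (NaN); estimates below ``mua_floor``
    are floored and counted.
    """
    ia_idx, ib_idx = gated.gate_set.pair(pair)
    i_a = gated.values[:, :, ia_idx, :]
    i_b = gated.values[:, :, ib_idx, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (i_a > 0) & (i_b > 0)
        log_ratio = np.where(ok, np.log(i_a) - np.log(i_b), np.nan)
    n_missing = int(np.size(ok) - np.count_nonzero(ok))

    v = props_prior.v_mm_per_ps
    centers = gated.gate_set.centers_ps
    if method == "interp":
        mu_grid, q_grid = _pair_inversion_table(
            gated.gate_set.gates[ia_idx],
            gated.gate_set.gates[ib_idx],
            props_prior.musp,
            props_prior.n_tissue,
            props_prior.rho,
            boundary,
            mua_max,
            512,
            129,
        )
        mua = np.interp(log_ratio, q_grid, mu_grid)
    elif method == "midpoint":
        m = reflectance_mua_free(centers[[ia_idx, ib_idx]], props_prior, boundary)
        offset = np.log(m[0] / m[1])
        mua = (log_ratio - offset) / (v * (centers[ib_idx] - centers[ia_idx]))
    else:
        raise ValueError("method must be 'interp' or 'midpoint'")

    low = np.isfinite(mua) & (mua < mua_floor)
    mua = np.where(low, mua_floor, mua)
    mua = np.where(np.isfinite(log_ratio), mua, np.nan)
    return MuaEstimate(
        values=mua,
        pair=pair,
        wavelengths_nm=gated.wavelengths_nm,
        channel_ids=gated.channel_ids,
        frame_times_s=gated.frame_times_s,
        n_floored=int(np.count_nonzero(low)),
        n_missing=n_missing,
    )


def hemoglobin_from_mua(mua: np.ndarray, wavelengths: tuple[float, float], ext: ExtinctionTable) -> np.ndarray:
    """Solve E @ [HbO, HbR] = mua per frame; returns (ch, 2, T) in uM."""
    e_inv = np.linalg.inv(ext.matrix(wavelengths))
    return np.einsum("ij,cjt->cit", e_inv, mua)


def rhbo_series(
    mua: MuaEstimate,
    baseline_window: tuple[float, float],
    ext: ExtinctionTable | None = None,
    protocol: TaskProtocol | None = None,
) -> HbOSeries:
    """Task-rest oxyhemoglobin ratio from delay-pair absorption estimates.

    Absolute [HbO](t) is recovered from the two-wavelength absorption
    through the extinction system, then divided by its rest-baseline mean,
    so the baseline mean of the output is 1 by construction.  Channels with
    nonpositive baseline HbO are flagged unusable.
    """
    ext = ext or ExtinctionTable.default()
    if len(mua.wavelengths_nm) != 2:
        raise ValueError("RHbO derivation requires exactly two wavelengths")
    conc = hemoglobin_from_mua(mua.values, tuple(mua.wavelengths_nm), ext)
    hbo = conc[:, 0, :]
    base = (mua.frame_times_s >= baseline_window[0]) & (mua.frame_times_s < baseline_window[1])
    if not np.any(base):
        raise ValueError("baseline window contains no frames")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base_mean = np.nanmean(hbo[:, base], axis=1)
    bad = ~(np.isfinite(base_mean) & (base_mean > 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = hbo / base_mean[:, np.newaxis]
    values[bad] = np.nan
    return HbOSeries(
        kind=RHBO,
        index=mua.pair,
        values=values,
        frame_times_s=mua.frame_times_s,
        channel_ids=mua.channel_ids,
        protocol=protocol,
        bad_channels=frozenset(np.array(mua.channel_ids)[bad].tolist()),
    )
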