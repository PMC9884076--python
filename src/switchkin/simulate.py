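"""Ground-truth-labelled single-molecule blinking simulator.

Emulates a dSTORM acquisition of sparse, surface-immobilised fluorophores:
molecules are scattered uniformly over a square field of view, each blinks
as a continuous-time two-state (on/off) process, and the local excitation
intensity sets both the expected spot brightness and — through it — the
switching rates:

* expected brightness        ``R = brightness_coeff * I(x, y)``  [photons/frame]
* off-switching rate         ``k_off = R / (N_tau_on * frame_time)``  [s⁻¹]
  (so the mean photons emitted per on-event equal the photon budget N_τon)
* on-switching (recovery)    ``k_on = k_on0 + beta_on * R``  [s⁻¹]
  (thermal recovery plus a photoinduced component linear in brightness)

Dwell times in both states are exponential.  Per-frame photon counts are
the fractional temporal overlap of on-events with the frame times R, with
shot noise whose variance is inflated by an EMCCD excess-noise factor
(gamma–Poisson mixture, variance = factor × mean).

Everything is reproducible bit-for-bit under ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chemistry import BufferCondition

__all__ = [
    "IlluminationMap",
    "KineticGroundTruth",
    "SimulationConfig",
    "MoleculeTrace",
    "make_illumination_map",
    "simulate_traces",
    "localization_table",
    "write_localization_table",
    "read_localization_table",
    "simulate_acidification_series",
]

LOCALIZATION_COLUMNS = ["frame", "x_nm", "y_nm", "photons"]


@dataclass
class IlluminationMap:
    """Excitation-intensity field over a square FOV.

    ``mems_gradient`` mimics a MEMS-micromirror scan profile: an isotropic
    Gaussian peaking at the FOV centre and attenuating toward the edges,
    parameterised by the intensity fraction remaining at the field corner.
    ``flat`` is a constant flat-field (beam-shaper) illumination.
    """

    field_size_um: float
    grid_shape: tuple[int, int]
    intensity_kW_cm2: np.ndarray
    mode: str
    peak_kW_cm2: float
    edge_fraction: float | None = None

    def intensity_at(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Continuous (analytic) intensity at FOV coordinates, kW/cm²."""
        x = np.asarray(x_um, dtype=float)
        y = np.asarray(y_um, dtype=float)
        if self.mode == "flat":
            return np.full(np.broadcast(x, y).shape, self.peak_kW_cm2)
        c = self.field_size_um / 2.0
        r2 = (x - c) ** 2 + (y - c) ** 2
        r_corner2 = 2.0 * c**2
        # corner value = edge_fraction * peak fixes the Gaussian width
        s2 = r_corner2 / (2.0 * np.log(1.0 / self.edge_fraction))
        return self.peak_kW_cm2 * np.exp(-r2 / (2.0 * s2))


def make_illumination_map(
    mode: str = "mems_gradient",
    peak_kW_cm2: float = 0.48,
    field_size_um: float = 62.5,
    grid_shape: tuple[int, int] = (49, 49),
    edge_fraction: float = 0.2,
) -> IlluminationMap:
    """Build an illumination field.

    Parameters
    ----------
    mode : {"mems_gradient", "flat"}
    peak_kW_cm2 : float
        Peak (centre) intensity; 0.48 kW/cm² is a typical single-molecule
        setting, 0.72 kW/cm² a typical flat-field cell setting.
    edge_fraction : float
        For ``mems_gradient``: intensity at the field corner as a fraction
        of the peak, in (0, 1).
    """
    if peak_kW_cm2 <= 0:
        raise ValueError("peak_kW_cm2 must be > 0")
    if field_size_um <= 0:
        raise ValueError("field_size_um must be > 0")
    if mode == "flat":
        grid = np.full(grid_shape, peak_kW_cm2)
        return IlluminationMap(field_size_um, tuple(grid_shape), grid, mode, peak_kW_cm2)
    if mode == "mems_gradient":
        if not 0.0 < edge_fraction < 1.0:
            raise ValueError("edge_fraction must be in (0, 1)")
        m = IlluminationMap(
            field_size_um, tuple(grid_shape), np.empty(grid_shape), mode,
            peak_kW_cm2, edge_fraction,
        )
        nx, ny = grid_shape
        xc = (np.arange(nx) + 0.5) * field_size_um / nx
        yc = (np.arange(ny) + 0.5) * field_size_um / ny
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        m.intensity_kW_cm2 = m.intensity_at(xx, yy)
        return m
    raise ValueError(f"unknown illumination mode {mode!r}")


@dataclass
class KineticGroundTruth:
    """True kinetic parameters of the simulated fluorophore/buffer pair.

    Defaults are a realistic mid-band thiolate condition for a cyanine
    photoswitch: photon budget 6,000 photons per on-event, thermal
    off-state lifetime 300 s, and a weak photoinduced recovery component.
    """

    N_tau_on: float = 6000.0                # photons per on-event
    k_on0_per_s: float = 1.0 / 300.0        # thermal recovery rate, s⁻¹
    beta_on: float = 2.0e-5                 # s⁻¹ per (photon/frame)
    brightness_coeff: float = 1667.0        # photons/frame per (kW/cm²)

    def __post_init__(self) -> None:
        for name in ("N_tau_on", "k_on0_per_s", "brightness_coeff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.beta_on < 0:
            raise ValueError("beta_on must be >= 0")

    @property
    def tau_off0_s(self) -> float:
        return 1.0 / self.k_on0_per_s


@dataclass
class SimulationConfig:
    """Acquisition geometry and noise settings.

    Defaults mirror a standard benchmark acquisition: 30,000 frames at
    20 Hz over a (62.5 µm)² FOV with ~5 molecules/µm², EMCCD excess-noise
    factor 2.
    """

    n_frames: int = 30000
    frame_time_s: float = 0.05
    field_size_um: float = 62.5
    density_per_um2: float = 5.0
    seed: int = 0
    excess_noise_factor: float = 2.0
    background_b2_photons: float = 49.0
    sigma_loc_nm: float = 0.0       # optional isotropic localization error
    bleach_rate_per_s: float = 0.0  # irreversible loss; off by default

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_time_s <= 0:
            raise ValueError("frame_time_s must be > 0")
        if self.field_size_um <= 0:
            raise ValueError("zero-area FOV")
        if self.density_per_um2 < 0:
            raise ValueError("density_per_um2 must be >= 0")
        if self.excess_noise_factor < 1:
            raise ValueError("excess_noise_factor must be >= 1")


@dataclass
class MoleculeTrace:
    """One emitter's trajectory through an acquisition.

    Per-frame photons are stored sparsely (``frames``/``photons`` hold the
    frames with nonzero signal, 1-based); ``frame_photons`` densifies on
    demand.  Continuous-time ground truth is kept alongside: completed
    on/off dwell durations in seconds and the on-intervals themselves.
    """

    molecule_id: int
    position_um: tuple[float, float]
    n_frames: int
    frames: np.ndarray               # 1-based frame indices with photons > 0
    photons: np.ndarray              # photon counts for those frames
    true_dwells_on: np.ndarray       # completed on dwells, s
    true_dwells_off: np.ndarray      # completed (interior) off dwells, s
    on_intervals_s: np.ndarray       # (n_events, 2) continuous on intervals
    expected_photons_per_frame: float

    @property
    def frame_photons(self) -> np.ndarray:
        dense = np.zeros(self.n_frames, dtype=float)
        dense[self.frames - 1] = self.photons
        return dense

    def true_state_path(self, frame_time_s: float) -> np.ndarray:
        """Boolean per-frame path: True where the molecule was on at all."""
        on = np.zeros(self.n_frames, dtype=bool)
        for t0, t1 in self.on_intervals_s:
            f0 = int(t0 / frame_time_s)
            f1 = min(int(np.nextafter(t1, t0) / frame_time_s), self.n_frames - 1)
            on[f0 : f1 + 1] = True
        return on

    @property
    def total_photons(self) -> float:
        return float(self.photons.sum())


def _sample_dwell_sequences(
    rng: np.random.Generator,
    k_off: np.ndarray,
    k_on: np.ndarray,
    T: float,
    bleach_rate: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alternating exponential dwells for all molecules at once.

    All molecules start in the off state at t = 0.  Returns flat arrays
    (molecule index, on-interval start, on-interval end) with ends clipped
    to the acquisition window; the last interval of a molecule may be
    right-censored at T.
    """
    n = k_off.size
    t = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    mol = np.arange(n)
    out_m: list[np.ndarray] = []
    out_t0: list[np.ndarray] = []
    out_t1: list[np.ndarray] = []
    while True:
        active = alive & (t < T)
        if not active.any():
            break
        idx = mol[active]
        # off dwell then on dwell for every active molecule
        t_on_start = t[idx] + rng.exponential(1.0 / k_on[idx])
        dur_on = rng.exponential(1.0 / k_off[idx])
        if bleach_rate > 0:
            bleached = rng.random(idx.size) < (
                1.0 - np.exp(-bleach_rate * dur_on)
            )
        t_on_end = t_on_start + dur_on
        visible = t_on_start < T
        out_m.append(idx[visible])
        out_t0.append(t_on_start[visible])
        out_t1.append(np.minimum(t_on_end[visible], T))
        t[idx] = t_on_end
        if bleach_rate > 0:
            alive[idx[bleached]] = False
    if out_m:
        return (np.concatenate(out_m), np.concatenate(out_t0), np.concatenate(out_t1))
    return (np.empty(0, dtype=int), np.empty(0), np.empty(0))


def _noisy_counts(rng: np.random.Generator, mean: np.ndarray, factor: float) -> np.ndarray:
    """Photon counts with variance = factor × mean (gamma–Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    if factor <= 1.0:
        return rng.poisson(mean).astype(float)
    lam = rng.gamma(shape=mean / (factor - 1.0), scale=factor - 1.0)
    return rng.poisson(lam).astype(float)


def simulate_traces(
    config: SimulationConfig,
    illum: IlluminationMap,
    truth: KineticGroundTruth,
) -> list[MoleculeTrace]:
    """Simulate all molecules of one acquisition.

    Molecule count is Poisson(density × area); positions uniform over the
    FOV.  See the module docstring for the kinetic model.  Molecules that
    never switch on within the window are returned with empty ``frames``
    (they carry censoring information for off-state estimation).
    """
    rng = np.random.default_rng(config.seed)
    area = config.field_size_um**2
    n_mol = int(rng.poisson(config.density_per_um2 * area))
    x = rng.uniform(0.0, config.field_size_um, n_mol)
    y = rng.uniform(0.0, config.field_size_um, n_mol)
    R = truth.brightness_coeff * illum.intensity_at(x, y)  # photons/frame
    dt = config.frame_time_s
    T = config.n_frames * dt
    k_off = R / (truth.N_tau_on * dt)          # s⁻¹
    k_on = truth.k_on0_per_s + truth.beta_on * R
    if np.any(k_off <= 0) or np.any(k_on <= 0):
        raise ValueError("non-positive switching rates")

    m, t0, t1 = _sample_dwell_sequences(rng, k_off, k_on, T, config.bleach_rate_per_s)
    order = np.lexsort((t0, m))
    m, t0, t1 = m[order], t0[order], t1[order]

    # map on-intervals onto frames with fractional overlap
    eps = 1e-12
    f0 = np.floor(t0 / dt).astype(np.int64)
    f1 = np.floor(np.minimum(t1, T - eps) / dt).astype(np.int64)
    counts = f1 - f0 + 1
    row_event = np.repeat(np.arange(m.size), counts)
    row_frame = f0[row_event] + (
        np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    )
    lo = np.maximum(t0[row_event], row_frame * dt)
    hi = np.minimum(t1[row_event], (row_frame + 1) * dt)
    frac = np.clip((hi - lo) / dt, 0.0, 1.0)
    mean_photons = frac * R[m[row_event]]

    # aggregate expected photons per (molecule, frame) before adding noise
    key = m[row_event].astype(np.int64) * config.n_frames + row_frame
    uniq, inv = np.unique(key, return_inverse=True)
    agg_mean = np.zeros(uniq.size)
    np.add.at(agg_mean, inv, mean_photons)
    photons = _noisy_counts(rng, agg_mean, config.excess_noise_factor)
    mol_of = (uniq // config.n_frames).astype(int)
    frame_of = (uniq % config.n_frames).astype(int) + 1  # 1-based

    # completed dwells per molecule (both endpoints inside the window)
    complete_on = t1 < T - eps
    # interior off dwell = gap between consecutive visible on-events of a molecule
    off_durs = t0[1:] - t1[:-1]

    traces: list[MoleculeTrace] = []
    mol_slices = np.searchsorted(mol_of, np.arange(n_mol + 1))
    ev_slices = np.searchsorted(m, np.arange(n_mol + 1))
    for i in range(n_mol):
        a, b = mol_slices[i], mol_slices[i + 1]
        ea, eb = ev_slices[i], ev_slices[i + 1]
        # gaps between this molecule's consecutive events live at [ea, eb-1)
        valid_off = off_durs[ea : eb - 1] if eb - ea >= 2 else np.empty(0)
        keep = frame_of[a:b][photons[a:b] > 0]
        traces.append(
            MoleculeTrace(
                molecule_id=i,
                position_um=(float(x[i]), float(y[i])),
                n_frames=config.n_frames,
                frames=keep,
                photons=photons[a:b][photons[a:b] > 0],
                true_dwells_on=(t1[ea:eb] - t0[ea:eb])[complete_on[ea:eb]],
                true_dwells_off=valid_off,
                on_intervals_s=np.column_stack((t0[ea:eb], t1[ea:eb])),
                expected_photons_per_frame=float(R[i]),
            )
        )
    return traces


def localization_table(
    traces: Iterable[MoleculeTrace],
    min_photons_threshold: float = 0.0,
    sigma_loc_nm: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Flatten traces to a localization table.

    One row per (molecule, frame) with photons ≥ threshold; columns
    ``frame`` (1-based), ``x_nm``, ``y_nm``, ``photons``; sorted by frame
    then molecule.  Optional isotropic Gaussian localization error.
    """
    rng = np.random.default_rng(seed)
    rows_frame, rows_x, rows_y, rows_p, rows_m = [], [], [], [], []
    for tr in traces:
        sel = tr.photons >= min_photons_threshold if min_photons_threshold > 0 else slice(None)
        f = tr.frames[sel]
        p = tr.photons[sel]
        n = f.size
        if n == 0:
            continue
        x_nm = np.full(n, tr.position_um[0] * 1000.0)
        y_nm = np.full(n, tr.position_um[1] * 1000.0)
        if sigma_loc_nm > 0:
            x_nm = x_nm + rng.normal(0.0, sigma_loc_nm, n)
            y_nm = y_nm + rng.normal(0.0, sigma_loc_nm, n)
        rows_frame.append(f)
        rows_x.append(x_nm)
        rows_y.append(y_nm)
        rows_p.append(p)
        rows_m.append(np.full(n, tr.molecule_id))
    if not rows_frame:
        return pd.DataFrame(columns=LOCALIZATION_COLUMNS)
    df = pd.DataFrame(
        {
            "frame": np.concatenate(rows_frame).astype(int),
            "x_nm": np.concatenate(rows_x),
            "y_nm": np.concatenate(rows_y),
            "photons": np.concatenate(rows_p),
            "_mol": np.concatenate(rows_m).astype(int),
        }
    )
    df = df.sort_values(["frame", "_mol"], kind="stable").drop(columns="_mol")
    return df.reset_index(drop=True)


def write_localization_table(
    table: pd.DataFrame | Iterable[MoleculeTrace],
    path: str | Path,
    min_photons_threshold: float = 0.0,
) -> Path:
    """Write a localization CSV (header ``frame,x_nm,y_nm,photons``, LF)."""
    if not isinstance(table, pd.DataFrame):
        table = localization_table(table, min_photons_threshold)
    path = Path(path)
    table.to_csv(path, index=False, lineterminator="\n", float_format="%.6g")
    return path


def read_localization_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LOCALIZATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"localization table missing columns: {sorted(missing)}")
    return df[LOCALIZATION_COLUMNS]


def simulate_acidification_series(
    buffer0: BufferCondition,
    drift_pH_per_h: float,
    timepoints_h: Sequence[float],
    calibration: Mapping[float, tuple[float, float]] | Callable[[float], tuple[float, float]],
    pH_floor: float = 4.0,
) -> pd.DataFrame:
    """Kinetics time-course under gluconic-acid buffer acidification.

    An unsealed glucose-oxidase chamber acidifies roughly linearly (about
    one pH unit per 2 h); sealing slows this ~10-fold.  pH(t) = pH₀ −
    drift·t (floored), thiolate follows Henderson–Hasselbalch, and the
    per-timepoint (τ_on, τ_off) are looked up from a calibration map
    keyed by thiolate concentration (mM), linearly interpolated.
    """
    if drift_pH_per_h < 0:
        raise ValueError("drift must be >= 0")
    if callable(calibration):
        lookup = calibration
    else:
        if not calibration:
            raise ValueError("empty calibration")
        keys = np.array(sorted(calibration))
        tau_on_v = np.array([calibration[k][0] for k in keys])
        tau_off_v = np.array([calibration[k][1] for k in keys])

        def lookup(th: float) -> tuple[float, float]:
            return (
                float(np.interp(th, keys, tau_on_v)),
                float(np.interp(th, keys, tau_off_v)),
            )

    rows = []
    for t in timepoints_h:
        pH = max(buffer0.pH - drift_pH_per_h * t, pH_floor)
        cond = BufferCondition(buffer0.thiol_total_mM, pH, buffer0.pKa)
        tau_on, tau_off = lookup(cond.thiolate_mM)
        rows.append(
            {
                "time_h": t,
                "pH": pH,
                "thiolate_mM": cond.thiolate_mM,
                "tau_on_ms": tau_on,
                "tau_off_s": tau_off,
            }
        )
    return pd.DataFrame(rows)
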