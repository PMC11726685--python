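"""Synthetic complex-valued fMRI runs with known ground truth.

The generator emulates the statistical structure of a submillimeter 2D-EPI
auditory run: ~230 volumes at TR 1.6 s; six tone-sequence conditions (two
presented 10 times per run, four presented 4 times, 36 trials total) in a
slow event-related design with inter-trial intervals of 5-7 TRs averaging
exactly 6; spatially varying thermal-noise amplification (g-factor); complex
Gaussian thermal noise (hence Rician magnitude); structured physiological
noise; and appended no-excitation noise scans that contain only the complex
noise term.

Each voxel's complex signal is

    S(v, t) = baseline * (1 + PSC(v, t)/100 + physio(v, t)/100) * exp(i phi(v, t))
              + g(v) * sigma * (xi1 + i xi2),      xi ~ N(0, 1)

where PSC is the ground-truth response amplitude convolved with the
canonical HRF at the trial onsets.  The ground-truth record (per-condition
response amplitudes, clean series, g-factor, cortical-depth and ROI labels)
is kept so that every downstream analysis can be validated against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .glm import build_design

__all__ = [
    "CONDITIONS",
    "DEFAULT_TRIALS_PER_CONDITION",
    "SimConfig",
    "EventDesign",
    "GroundTruth",
    "TimeSeries4D",
    "generate_design",
    "generate_gfactor",
    "generate_ground_truth",
    "synthesize_run",
    "save_run",
    "load_run",
]

#: condition labels: tone sequences ending in a high (H) or low (L) target
CONDITIONS = ("PredH", "PredL", "MispredH", "MispredL", "UnpredH", "UnpredL")

#: per-run trial counts: predictable sequences 10 each, the rest 4 each
DEFAULT_TRIALS_PER_CONDITION = {
    "PredH": 10, "PredL": 10,
    "MispredH": 4, "MispredL": 4,
    "UnpredH": 4, "UnpredL": 4,
}

#: four tones of 100 ms with 400 ms gaps
STIMULUS_DURATION_S = 1.6

N_DEPTHS = 11


@dataclass
class SimConfig:
    """Parameters of one simulated run (defaults are the study conditions)."""

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_volumes: int = 230
    n_noise_scans: int = 5
    tr_seconds: float = 1.6
    sigma_thermal: float = 1.5        # complex-noise std per channel (a.u.)
    physio_amplitude: float = 1.0     # structured-noise scale, percent of baseline
    gfactor_range: tuple[float, float] = (1.0, 2.5)
    baseline: float = 100.0           # mean magnitude signal (a.u.)
    seed: int = 0
    trials_per_condition: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TRIALS_PER_CONDITION)
    )
    lead_in_volumes: int = 6
    lead_out_volumes: int = 6
    # ground-truth response structure
    psc_amplitude: float = 2.5        # mean response, percent signal change
    psc_spatial_rel_sd: float = 1.0   # smooth multiplicative spatial variation
    tonotopy_contrast: float = 0.4    # preferred vs non-preferred scaling
    depth_ramp: tuple[float, float] = (0.6, 1.6)  # deep -> superficial scaling

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.n_volumes < 1 or self.n_noise_scans < 0:
            raise ValueError("invalid volume counts")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.sigma_thermal < 0:
            raise ValueError("sigma_thermal must be non-negative")
        if self.physio_amplitude < 0:
            raise ValueError("physio_amplitude must be non-negative")
        lo, hi = self.gfactor_range
        if lo < 1 or hi < lo:
            raise ValueError("gfactor_range must satisfy 1 <= low <= high")
        unknown = set(self.trials_per_condition) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")

    @property
    def n_trials(self) -> int:
        return sum(self.trials_per_condition.values())


@dataclass
class EventDesign:
    """Ordered trial list of one run: (condition, onset volume) pairs."""

    trials: list[tuple[str, int]]
    tr_seconds: float
    stimulus_duration_s: float = STIMULUS_DURATION_S

    @property
    def onsets(self) -> np.ndarray:
        return np.array([onset for _, onset in self.trials], dtype=int)

    @property
    def conditions(self) -> list[str]:
        return [c for c, _ in self.trials]

    def condition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c, _ in self.trials:
            counts[c] = counts.get(c, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset": self.onsets * self.tr_seconds,
            "duration": self.stimulus_duration_s,
            "trial_type": self.conditions,
            "onset_volume": self.onsets,
        })


@dataclass
class GroundTruth:
    """The simulator's truth record for one subject."""

    beta_true: np.ndarray        # (x, y, z, n_conditions), percent signal
    gfactor: np.ndarray          # (x, y, z), >= 1
    depth_labels: np.ndarray     # int 1..11 inside the ROI, 0 elsewhere
    roi_labels: np.ndarray       # int ROI id per voxel (0 = background)
    condition_names: tuple[str, ...] = CONDITIONS
    signal_clean: np.ndarray | None = None  # filled in by synthesize_run

    def beta_of(self, condition: str) -> np.ndarray:
        return self.beta_true[..., self.condition_names.index(condition)]


@dataclass
class TimeSeries4D:
    """4D magnitude (+ optional phase) series with appended noise scans."""

    magnitude: np.ndarray            # (x, y, z, t), non-negative
    phase: np.ndarray | None         # radians, same shape, or None
    tr_seconds: float
    n_noise_scans_appended: int = 0

    def __post_init__(self):
        if self.magnitude.ndim != 4:
            raise ValueError("magnitude must be 4D (x, y, z, t)")
        if self.phase is not None and self.phase.shape != self.magnitude.shape:
            raise ValueError("phase must match magnitude shape")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape[:3]

    @property
    def n_volumes_total(self) -> int:
        return self.magnitude.shape[3]

    @property
    def n_data_volumes(self) -> int:
        return self.n_volumes_total - self.n_noise_scans_appended

    def complex_data(self) -> np.ndarray:
        """Complex series; requires phase."""
        if self.phase is None:
            raise ValueError("phase is not available")
        return self.magnitude * np.exp(1j * self.phase)

    def data_volumes(self) -> "TimeSeries4D":
        """The functional volumes with noise scans stripped."""
        n = self.n_data_volumes
        return TimeSeries4D(
            magnitude=self.magnitude[..., :n],
            phase=None if self.phase is None else self.phase[..., :n],
            tr_seconds=self.tr_seconds,
            n_noise_scans_appended=0,
        )

    def noise_volumes(self) -> "TimeSeries4D":
        if self.n_noise_scans_appended == 0:
            raise ValueError("no appended noise scans")
        n = self.n_data_volumes
        return TimeSeries4D(
            magnitude=self.magnitude[..., n:],
            phase=None if self.phase is None else self.phase[..., n:],
            tr_seconds=self.tr_seconds,
            n_noise_scans_appended=self.magnitude.shape[3] - n,
        )


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), tag])


def _smooth_field(shape, rng, smooth_vox: float = 3.0) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian-filtered white noise field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_vox, mode="nearest")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_design(config: SimConfig, seed_offset: int = 0) -> EventDesign:
    """Randomized trial order with inter-trial intervals from {5, 6, 7} TRs.

    The interval multiset holds equally many 5s and 7s (the remainder are
    6s), so the mean interval is exactly 6 TRs; the condition order and the
    interval order are independent seeded permutations.  ``seed_offset``
    lets several runs of one subject draw distinct orders.
    """
    rng = np.random.default_rng([int(config.seed) % (2**31), 1, int(seed_offset)])
    conditions = [c for c in CONDITIONS for _ in range(config.trials_per_condition.get(c, 0))]
    n = len(conditions)
    if n < 1:
        raise ValueError("design has no trials")
    rng.shuffle(conditions)
    n_gaps = n - 1
    k = (n_gaps + 1) // 3
    gaps = np.array([5] * k + [7] * k + [6] * (n_gaps - 2 * k), dtype=int)
    rng.shuffle(gaps)
    onsets = config.lead_in_volumes + np.concatenate([[0], np.cumsum(gaps)])
    if onsets[-1] + config.lead_out_volumes >= config.n_volumes:
        raise ValueError(
            f"{n} trials need {onsets[-1] + config.lead_out_volumes + 1} volumes "
            f"(lead-in {config.lead_in_volumes}, lead-out {config.lead_out_volumes}); "
            f"run has only {config.n_volumes}"
        )
    trials = list(zip(conditions, (int(o) for o in onsets)))
    return EventDesign(trials=trials, tr_seconds=config.tr_seconds)


def generate_gfactor(config: SimConfig) -> np.ndarray:
    """Smooth spatial noise-amplification map with values in gfactor_range."""
    lo, hi = config.gfactor_range
    if lo < 1:
        raise ValueError("g-factor must be >= 1 everywhere")
    if hi == lo:
        return np.full(config.grid_shape, float(lo))
    f = _smooth_field(config.grid_shape, _rng(config, 2), smooth_vox=max(config.grid_shape) / 4)
    f = (f - f.min()) / (f.max() - f.min())
    return lo + (hi - lo) * f


def _roi_box(shape) -> tuple[slice, slice, slice]:
    margins = [max(1, s // 8) for s in shape]
    return tuple(slice(m, s - m) for m, s in zip(margins, shape))


def generate_ground_truth(config: SimConfig) -> GroundTruth:
    """Ground-truth responses, g-factor, ROI and cortical-depth labels.

    The ROI is a central block standing in for the temporal-lobe mask.  Depth
    labels 1..11 run along the first axis inside the ROI (1 = deep,
    11 = superficial); the response amplitude ramps deep -> superficial as in
    GE-BOLD laminar profiles.  A low/high/low frequency-preference band
    pattern along the second axis scales conditions ending in the preferred
    target frequency up and the others down.
    """
    shape = tuple(config.grid_shape)
    rng = _rng(config, 3)
    gfactor = generate_gfactor(config)

    roi = np.zeros(shape, dtype=int)
    box = _roi_box(shape)
    roi[box] = 1

    depth = np.zeros(shape, dtype=int)
    x0, x1 = box[0].start, box[0].stop  # depth axis extent within the ROI
    xs = np.arange(shape[0])
    frac = np.clip((xs - x0) / max(x1 - x0, 1), 0, 1 - 1e-9)
    depth_of_x = (1 + np.floor(frac * N_DEPTHS)).astype(int)
    depth[:] = depth_of_x[:, None, None]
    depth[roi == 0] = 0

    amp = config.psc_amplitude * np.clip(
        1.0 + config.psc_spatial_rel_sd * _smooth_field(shape, rng), 0.2, None
    )
    lo_scale, hi_scale = config.depth_ramp
    ramp = np.ones(shape)
    inside = depth > 0
    ramp[inside] = lo_scale + (hi_scale - lo_scale) * (depth[inside] - 1) / (N_DEPTHS - 1)

    # low/high/low preference bands along axis 1
    ys = np.arange(shape[1])
    band = (ys >= shape[1] / 3) & (ys < 2 * shape[1] / 3)  # central band prefers high
    prefers_high = np.zeros(shape, dtype=bool)
    prefers_high[:] = band[None, :, None]

    c = config.tonotopy_contrast
    beta_true = np.zeros(shape + (len(CONDITIONS),))
    for k, cond in enumerate(CONDITIONS):
        is_high = cond.endswith("H")
        pref = prefers_high if is_high else ~prefers_high
        scale = np.where(pref, 1.0 + c, 1.0 - c)
        beta_true[..., k] = amp * ramp * scale
    beta_true[roi == 0] = 0.0
    return GroundTruth(beta_true=beta_true, gfactor=gfactor, depth_labels=depth,
                       roi_labels=roi)


def _physio(config: SimConfig, n_volumes: int, rng) -> np.ndarray:
    """Structured noise in percent units: drift + two sinusoids + AR(1).

    The drift and the respiratory- (0.3 Hz) and cardiac-like (1.0 Hz,
    aliased by the TR) sinusoids share spatially smooth weight maps.  The
    AR(1) term (rho = 0.3, stationary std a/2) is temporally autocorrelated
    per voxel but spatially coherent (smoothed innovations): physiological
    fluctuations are structured in space, unlike thermal noise, which is
    what distinguishes them from the noise a thermal-noise threshold should
    remove.
    """
    shape = tuple(config.grid_shape)
    a = config.physio_amplitude
    if a == 0:
        return np.zeros(shape + (n_volumes,))
    t = np.arange(n_volumes) * config.tr_seconds
    drift = np.linspace(-1.0, 1.0, n_volumes)
    resp = np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    card = np.sin(2 * np.pi * 1.0 * t + rng.uniform(0, 2 * np.pi))
    out = np.zeros(shape + (n_volumes,))
    for course in (drift, resp, card):
        w = a * 0.5 * _smooth_field(shape, rng)
        out += w[..., None] * course[None, None, None, :]
    rho = 0.3
    innov = rng.standard_normal(shape + (n_volumes,))
    innov = ndimage.gaussian_filter(innov, sigma=(2.0, 2.0, 2.0, 0.0), mode="nearest")
    innov /= innov.std()
    innov *= (a / 2) * np.sqrt(1 - rho**2)
    ar = np.empty_like(innov)
    ar[..., 0] = innov[..., 0] / np.sqrt(1 - rho**2)
    for i in range(1, n_volumes):
        ar[..., i] = rho * ar[..., i - 1] + innov[..., i]
    return out + ar


def synthesize_run(
    design: EventDesign,
    truth: GroundTruth,
    config: SimConfig,
    run_seed_tag: int = 0,
) -> TimeSeries4D:
    """Simulate one complex-valued run plus appended noise scans.

    The noiseless magnitude (baseline scaled by the HRF-convolved true
    responses) is stored in ``truth.signal_clean``.  Appended noise scans
    contain only the complex thermal-noise term.
    """
    if config.sigma_thermal < 0:
        raise ValueError("sigma_thermal must be non-negative")
    shape = tuple(config.grid_shape)
    if truth.beta_true.shape[:3] != shape:
        raise ValueError("ground truth does not match grid_shape")
    T = config.n_volumes
    rng = np.random.default_rng([int(config.seed) % (2**31), 4, int(run_seed_tag)])

    dm = build_design(design, T)
    cond_idx = np.array([CONDITIONS.index(c) for c in dm.condition_of_trial])
    # PSC(v, t) = sum over trials of X[t, k] * beta_true[v, condition(k)]
    trial_betas = truth.beta_true[..., cond_idx]          # (x, y, z, n_trials)
    psc = np.einsum("tk,xyzk->xyzt", dm.X[:, :-1], trial_betas)

    clean = config.baseline * (1.0 + psc / 100.0)
    truth.signal_clean = clean
    physio = _physio(config, T, rng)
    amp = config.baseline * (1.0 + psc / 100.0 + physio / 100.0)

    # smooth static spatial phase plus a small slow temporal modulation
    phase_rng = _rng(config, 5)
    phi0 = 0.5 * _smooth_field(shape, phase_rng)
    psi = 0.02 * _smooth_field(shape, phase_rng)
    t_s = np.arange(T) * config.tr_seconds
    phi = phi0[..., None] + psi[..., None] * np.sin(2 * np.pi * 0.05 * t_s)[None, None, None, :]

    total = T + config.n_noise_scans
    g = truth.gfactor
    noise = (config.sigma_thermal * g[..., None]) * (
        rng.standard_normal(shape + (total,)) + 1j * rng.standard_normal(shape + (total,))
    )
    signal = np.zeros(shape + (total,), dtype=complex)
    signal[..., :T] = amp * np.exp(1j * phi)
    s = signal + noise
    return TimeSeries4D(
        magnitude=np.abs(s),
        phase=np.angle(s),
        tr_seconds=config.tr_seconds,
        n_noise_scans_appended=config.n_noise_scans,
    )


# ---------------------------------------------------------------------------
# IO: NIfTI volumes, events tables, truth archives, YAML configs


def _nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data), affine=np.eye(4))


def save_run(ts: TimeSeries4D, design: EventDesign, outdir, prefix: str = "run",
             truth: GroundTruth | None = None) -> dict[str, str]:
    """Write magnitude/phase NIfTIs, an events TSV and the truth archive."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    mag_path = outdir / f"{prefix}_mag.nii"
    nib.save(_nifti(ts.magnitude), mag_path)
    paths["magnitude"] = str(mag_path)
    if ts.phase is not None:
        phase_path = outdir / f"{prefix}_phase.nii"
        nib.save(_nifti(ts.phase), phase_path)
        paths["phase"] = str(phase_path)
    events_path = outdir / f"{prefix}_events.tsv"
    design.to_frame().to_csv(events_path, sep="\t", index=False)
    paths["events"] = str(events_path)
    meta_path = outdir / f"{prefix}_meta.json"
    meta_path.write_text(json.dumps({
        "tr_seconds": ts.tr_seconds,
        "n_noise_scans_appended": ts.n_noise_scans_appended,
    }))
    paths["meta"] = str(meta_path)
    if truth is not None:
        truth_path = outdir / f"{prefix}_truth.npz"
        np.savez_compressed(
            truth_path,
            beta_true=truth.beta_true,
            gfactor=truth.gfactor,
            depth_labels=truth.depth_labels,
            roi_labels=truth.roi_labels,
            condition_names=np.array(truth.condition_names),
        )
        paths["truth"] = str(truth_path)
    return paths


def load_run(mag_path, phase_path=None, events_path=None, meta_path=None):
    """Load a run written by :func:`save_run`.

    Returns ``(TimeSeries4D, EventDesign | None)``.
    """
    mag = np.asarray(nib.load(str(mag_path)).dataobj, dtype=float)
    phase = None
    if phase_path is not None:
        phase = np.asarray(nib.load(str(phase_path)).dataobj, dtype=float)
    tr, n_noise = 1.6, 0
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
        tr = float(meta["tr_seconds"])
        n_noise = int(meta["n_noise_scans_appended"])
    ts = TimeSeries4D(magnitude=mag, phase=phase, tr_seconds=tr,
                      n_noise_scans_appended=n_noise)
    design = None
    if events_path is not None:
        frame = pd.read_csv(events_path, sep="\t")
        trials = list(zip(frame["trial_type"], frame["onset_volume"].astype(int)))
        design = EventDesign(trials=trials, tr_seconds=tr)
    return ts, design
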