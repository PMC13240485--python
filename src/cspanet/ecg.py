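"""Synthetic 12-lead ECG waveforms, report-style images, and dataset plumbing.

The clinical dataset behind this task (sinus-rhythm ECG printouts of
healthy controls, concealed-accessory-pathway and AVNRT patients) is
private, so this module provides a fully synthetic stand-in: 10-second,
12-lead recordings at 500 Hz built from Gaussian bumps (P, Q, R, S, T) on
a regular R-R lattice, projected to the 12 leads by fixed per-lead
amplitude factors, with optional baseline wander and white noise. Class
structure is injected as small parameter offsets:

* class 1 (CAP):   PR interval -12 ms, P-wave width +8 ms
* class 2 (AVNRT): P-wave amplitude -20 %, heart rate -3 bpm

mirroring the *direction* of resting-heart-rate differences seen between
AVNRT patients and controls. The model makes no claim of reproducing true
CAP/AVNRT electrophysiology — it exists so the labels carry a subtle but
learnable signal through the full image pipeline.

Wave "width" follows a fixed convention: the full width at 5 % of the
bump amplitude (sigma = width / (2 * sqrt(2 ln 20))), so a threshold
crossing at 5 % recovers wave onsets exactly and the PR interval
(P onset to QRS onset) is measurable on noiseless traces.

Records render to grayscale report images in the standard 4-column x
3-row layout (columns show consecutive 2.5-s windows), and preprocessing
reproduces the published pipeline: crop to the waveform bounding box,
bilinear rescale (half-pixel-center alignment) to a fixed resolution,
intensities in [0, 1]. Splitting is patient-disjoint and stratified by
class at a 7:3 ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigurationError, InputError

__all__ = [
    "LEAD_NAMES", "SynthConfig", "ECGRecord", "DatasetSplit",
    "sample_patient_params", "synthesize_record", "render_ecg_image",
    "preprocess_image", "split_patient_disjoint", "generate_dataset",
]

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")

# Fixed per-lead projection factors for the whole PQRST complex; aVR is
# inverted as on a real ECG. Values are a plausible, deliberately simple
# spread of limb/precordial amplitudes.
LEAD_FACTORS = {
    "I": 0.55, "II": 1.00, "III": 0.45, "aVR": -0.50, "aVL": 0.30, "aVF": 0.75,
    "V1": 0.40, "V2": 0.70, "V3": 0.90, "V4": 1.10, "V5": 1.00, "V6": 0.80,
}

FS = 500            # sampling frequency, Hz
DURATION_S = 10.0   # record length, s
N_SAMPLES = int(FS * DURATION_S)
WIDTH_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(20.0))  # width at 5 % amplitude


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters: waveform statistics, class effects, rendering.

    Waveform fields are (mean, sd) pairs sampled per patient; class-effect
    offsets shift them for labels 1 and 2. Standard deviations are kept
    narrow relative to the offsets so the class signal is subtle but
    learnable at desk-scale image resolution.
    """

    # per-patient base parameters: (mean, sd)
    heart_rate_bpm: tuple = (78.0, 1.0)
    pr_interval_ms: tuple = (150.0, 2.5)
    p_amp_mv: tuple = (0.25, 0.010)
    p_width_ms: tuple = (90.0, 2.5)
    qrs_amp_mv: tuple = (1.10, 0.05)
    qrs_width_ms: tuple = (85.0, 3.0)
    t_amp_mv: tuple = (0.32, 0.02)
    t_width_ms: tuple = (160.0, 6.0)

    # class-effect offsets (applied after sampling)
    cap_pr_offset_ms: float = -12.0
    cap_p_width_offset_ms: float = 8.0
    avnrt_p_amp_factor: float = 0.80
    avnrt_hr_offset_bpm: float = -3.0

    # noise
    noise_sd_mv: float = 0.01
    wander_amp_mv: float = 0.01
    wander_freq_hz: tuple = (0.15, 0.40)  # uniform range, per record

    # dataset shape
    n_patients: tuple = (100, 100, 100)
    ecgs_per_patient: int = 1
    split_ratio: float = 0.7
    seed: int = 7

    # image rendering
    canvas_size: tuple = (1600, 800)  # (W, H)
    grid: bool = False
    trace_thickness: int = 3
    cell_pad_px: int = 6
    px_per_mv: float = 100.0

    def __post_init__(self):
        for name in ("heart_rate_bpm", "pr_interval_ms", "p_amp_mv", "p_width_ms",
                     "qrs_amp_mv", "qrs_width_ms", "t_amp_mv", "t_width_ms"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ConfigurationError(f"{name} sd must be >= 0")
        if self.noise_sd_mv < 0 or self.wander_amp_mv < 0:
            raise ConfigurationError("noise amplitudes must be >= 0")
        if not (0 < self.split_ratio < 1):
            raise ConfigurationError("split_ratio must be in (0, 1)")
        if len(self.n_patients) != 3 or min(self.n_patients) < 0:
            raise ConfigurationError("n_patients must give a count per class")
        if self.trace_thickness < 1:
            raise ConfigurationError("trace_thickness must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        tup = {k: tuple(v) for k, v in d.items() if isinstance(v, list)}
        return cls(**{**d, **tup})


@dataclass
class ECGRecord:
    """One synthetic 12-lead recording plus its provenance."""
    patient_id: str
    label: int
    leads: dict            # lead name -> float array of N_SAMPLES
    heart_rate: float      # bpm, after class offsets
    pr_interval: float     # ms, after class offsets
    generation_params: dict

    def __post_init__(self):
        if set(self.leads) != set(LEAD_NAMES):
            raise InputError("record must contain exactly the 12 standard leads")
        for name, trace in self.leads.items():
            if np.asarray(trace).shape != (N_SAMPLES,):
                raise InputError(f"lead {name} must have {N_SAMPLES} samples")
        if not (30 < self.heart_rate < 220) or self.pr_interval <= 0:
            raise InputError("heart rate / PR interval outside physiological range")


@dataclass
class DatasetSplit:
    train: list
    test: list
    ratio: float
    seed: int


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

_CLIP_RANGES = {
    "heart_rate_bpm": (35.0, 200.0),
    "pr_interval_ms": (70.0, 320.0),
    "p_amp_mv": (0.02, 0.6),
    "p_width_ms": (40.0, 160.0),
    "qrs_amp_mv": (0.3, 3.0),
    "qrs_width_ms": (50.0, 160.0),
    "t_amp_mv": (0.05, 1.0),
    "t_width_ms": (80.0, 320.0),
}


def sample_patient_params(label: int, cfg: SynthConfig, rng) -> dict:
    """Draw one patient's waveform parameters and apply class offsets."""
    if label not in (0, 1, 2):
        raise InputError(f"label must be in {{0, 1, 2}}, got {label}")
    params = {}
    for name in _CLIP_RANGES:
        mean, sd = getattr(cfg, name)
        params[name] = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
    if label == 1:
        params["pr_interval_ms"] += cfg.cap_pr_offset_ms
        params["p_width_ms"] += cfg.cap_p_width_offset_ms
    elif label == 2:
        params["p_amp_mv"] *= cfg.avnrt_p_amp_factor
        params["heart_rate_bpm"] += cfg.avnrt_hr_offset_bpm
    for name, (lo, hi) in _CLIP_RANGES.items():
        if not (lo <= params[name] <= hi):
            warnings.warn(f"{name}={params[name]:.3g} clipped to [{lo}, {hi}]",
                          RuntimeWarning, stacklevel=2)
            params[name] = float(np.clip(params[name], lo, hi))
    return params


def _gauss(t: np.ndarray, centers: np.ndarray, amp: float, width_ms: float) -> np.ndarray:
    sigma = (width_ms / 1000.0) / WIDTH_TO_SIGMA
    out = np.zeros_like(t)
    for c in centers:
        lo = np.searchsorted(t, c - 6 * sigma)
        hi = np.searchsorted(t, c + 6 * sigma)
        out[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / sigma) ** 2)
    return out


def _beat_template(t: np.ndarray, r_centers: np.ndarray, p: dict) -> np.ndarray:
    """Sum of P, Q, R, S, T bumps for every beat, in mV, for the reference lead."""
    qrs_w = p["qrs_width_ms"]
    qrs_onset = r_centers - (qrs_w / 2) / 1000.0
    p_center = qrs_onset - (p["pr_interval_ms"] - p["p_width_ms"] / 2) / 1000.0
    trace = _gauss(t, p_center, p["p_amp_mv"], p["p_width_ms"])
    trace += _gauss(t, r_centers - (qrs_w / 3) / 1000.0, -0.15 * p["qrs_amp_mv"], qrs_w / 4)
    trace += _gauss(t, r_centers, p["qrs_amp_mv"], qrs_w / 2)
    trace += _gauss(t, r_centers + (qrs_w / 3) / 1000.0, -0.22 * p["qrs_amp_mv"], qrs_w / 4)
    trace += _gauss(t, r_centers + 0.30, p["t_amp_mv"], p["t_width_ms"])
    return trace


def synthesize_record(label: int, cfg: SynthConfig, rng,
                      patient_id: str = "P0000",
                      patient_params: dict | None = None) -> ECGRecord:
    """Build one 12-lead record; all randomness comes from ``rng``.

    ``patient_params`` (from :func:`sample_patient_params`) may be passed
    so several records share one patient's waveform parameters; noise and
    baseline wander are drawn fresh per record.
    """
    p = patient_params or sample_patient_params(label, cfg, rng)
    rr = 60.0 / p["heart_rate_bpm"]
    t = np.arange(N_SAMPLES) / FS
    first_r = 0.4
    n_beats = int(math.ceil((DURATION_S - first_r) / rr)) + 2
    r_centers = first_r + rr * np.arange(-1, n_beats)
    base = _beat_template(t, r_centers, p)

    leads = {}
    wander_f = float(rng.uniform(*cfg.wander_freq_hz))
    wander_phase = float(rng.uniform(0, 2 * math.pi))
    for name in LEAD_NAMES:
        trace = LEAD_FACTORS[name] * base
        if cfg.wander_amp_mv > 0:
            trace = trace + cfg.wander_amp_mv * np.sin(
                2 * math.pi * wander_f * t + wander_phase + 0.3 * LEAD_NAMES.index(name))
        if cfg.noise_sd_mv > 0:
            trace = trace + rng.normal(0.0, cfg.noise_sd_mv, size=N_SAMPLES)
        leads[name] = trace
    return ECGRecord(
        patient_id=patient_id, label=label, leads=leads,
        heart_rate=p["heart_rate_bpm"], pr_interval=p["pr_interval_ms"],
        generation_params={**p, "wander_freq_hz": wander_f,
                           "wander_phase": wander_phase, "label": label},
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_ecg_image(record: ECGRecord, cfg: SynthConfig, path=None) -> np.ndarray:
    """Render a record to a grayscale uint8 canvas (white background).

    Standard report layout: 4 columns x 3 rows, column-major lead order
    (I, II, III | aVR, aVL, aVF | V1-V3 | V4-V6); column c shows the
    c-th consecutive 2.5-s window. Deterministic given record and config.
    If ``path`` is given the canvas is also written as a PNG.
    """
    W, H = cfg.canvas_size
    cw, ch = W // 4, H // 3
    pad = cfg.cell_pad_px
    n_px = cw - 2 * pad
    if n_px < 8 or ch < 16:
        raise ConfigurationError(f"canvas {cfg.canvas_size} too small for the 4x3 layout")
    canvas = np.full((H, W), 255, dtype=np.uint8)
    if cfg.grid:
        canvas[::40, :] = 220
        canvas[:, ::40] = 220
    t_cell = DURATION_S / 4
    os_factor = 4
    up = (cfg.trace_thickness - 1) // 2
    down = cfg.trace_thickness - 1 - up
    for col in range(4):
        for row in range(3):
            lead = LEAD_NAMES[col * 3 + row]
            trace = np.asarray(record.leads[lead])
            x0 = col * cw + pad
            y0 = row * ch
            baseline = y0 + ch // 2
            # dense resample of this cell's 2.5-s window
            ts = col * t_cell + (np.arange(n_px * os_factor) + 0.5) * t_cell / (n_px * os_factor)
            vals = np.interp(ts * FS, np.arange(N_SAMPLES), trace)
            y = baseline - vals * cfg.px_per_mv
            yg = y.reshape(n_px, os_factor)
            gmin, gmax = yg.min(axis=1), yg.max(axis=1)
            gmin[1:] = np.minimum(gmin[1:], yg[:-1, -1])  # bridge adjacent columns
            gmax[1:] = np.maximum(gmax[1:], yg[:-1, -1])
            lo = np.clip(np.floor(gmin).astype(int) - up, y0, y0 + ch - 1)
            hi = np.clip(np.ceil(gmax).astype(int) + down, y0, y0 + ch - 1)
            rows_idx = np.arange(y0, y0 + ch)
            mask = (rows_idx[None, :] >= lo[:, None]) & (rows_idx[None, :] <= hi[:, None])
            cell = canvas[y0:y0 + ch, x0:x0 + n_px]
            cell[mask.T] = 0
    if path is not None:
        Image.fromarray(canvas, mode="L").save(path, format="PNG")
    return canvas


# ---------------------------------------------------------------------------
# Preprocessing (crop + bilinear rescale)
# ---------------------------------------------------------------------------

def _bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear resize with half-pixel-center alignment."""
    in_h, in_w = img.shape
    ys = np.clip((np.arange(out_h) + 0.5) * in_h / out_h - 0.5, 0, in_h - 1)
    xs = np.clip((np.arange(out_w) + 0.5) * in_w / out_w - 0.5, 0, in_w - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, in_h - 1)
    x1 = np.minimum(x0 + 1, in_w - 1)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    a = img[np.ix_(y0, x0)]
    b = img[np.ix_(y0, x1)]
    c = img[np.ix_(y1, x0)]
    d = img[np.ix_(y1, x1)]
    return (a * (1 - wy) * (1 - wx) + b * (1 - wy) * wx
            + c * wy * (1 - wx) + d * wy * wx)


def preprocess_image(image, target_size: tuple, margin: float = 0.02,
                     bg_threshold: float = 0.95) -> np.ndarray:
    """Crop to the waveform bounding box and bilinear-rescale to a fixed size.

    ``image`` is a grayscale array (uint8 0-255 or float); ``target_size``
    is (W, H). Foreground pixels are those darker than ``bg_threshold``
    (white background). The bounding box is expanded by ``margin`` x its
    size on each side before cropping. Output is float32 in [0, 1].
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:  # collapse accidental RGB
        img = img.mean(axis=2)
    if img.ndim != 2 or img.size == 0:
        raise InputError(f"expected a nonempty 2D grayscale image, got shape {img.shape}")
    if img.max() > 1.0:
        img = img / 255.0
    fg = img < bg_threshold
    if not fg.any():
        raise InputError("image has no foreground (everything is background-white)")
    rows = np.nonzero(fg.any(axis=1))[0]
    cols = np.nonzero(fg.any(axis=0))[0]
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    mr = int(math.ceil(margin * (r1 - r0)))
    mc = int(math.ceil(margin * (c1 - c0)))
    r0, r1 = max(0, r0 - mr), min(img.shape[0], r1 + mr)
    c0, c1 = max(0, c0 - mc), min(img.shape[1], c1 + mc)
    cropped = img[r0:r1, c0:c1]
    tw, th = target_size
    out = _bilinear_resize(cropped, th, tw)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Patient-disjoint splitting and dataset generation
# ---------------------------------------------------------------------------

def _assign_patients(patient_ids, labels, ratio: float, seed: int) -> dict:
    """Map patient_id -> 'train'/'test', stratified by class."""
    if not (0 < ratio < 1):
        raise InputError(f"ratio must be in (0, 1), got {ratio}")
    by_patient: dict = {}
    for pid, lab in zip(patient_ids, labels):
        if pid in by_patient and by_patient[pid] != lab:
            raise InputError(f"patient {pid!r} has records in multiple classes")
        by_patient[pid] = lab
    if len(by_patient) < 2:
        raise InputError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    assignment = {}
    for lab in sorted(set(by_patient.values())):
        pids = sorted(p for p, l in by_patient.items() if l == lab)
        rng.shuffle(pids)
        n_train = int(round(ratio * len(pids)))
        for i, pid in enumerate(pids):
            assignment[pid] = "train" if i < n_train else "test"
    return assignment


def split_patient_disjoint(records, ratio: float = 0.7, seed: int = 0) -> DatasetSplit:
    """Partition records so every patient's records land on one side.

    Patients (not records) are shuffled with a seeded generator and split
    per class, the train side receiving round(ratio * n_patients) patients
    of each class.
    """
    records = list(records)
    assignment = _assign_patients([r.patient_id for r in records],
                                  [r.label for r in records], ratio, seed)
    train = [r for r in records if assignment[r.patient_id] == "train"]
    test = [r for r in records if assignment[r.patient_id] == "test"]
    return DatasetSplit(train=train, test=test, ratio=ratio, seed=seed)


def generate_dataset(cfg: SynthConfig, out_dir) -> pd.DataFrame:
    """Synthesize, render, split, and write a complete image dataset.

    Writes one PNG per record plus ``manifest.csv`` with columns
    (file, patient_id, label, split). Fully reproducible from the config:
    the same config yields byte-identical images and manifest.
    """
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for label, n_pat in enumerate(cfg.n_patients):
        for i in range(n_pat):
            pid = f"C{label}P{i:04d}"
            params = sample_patient_params(label, cfg, rng)
            for j in range(cfg.ecgs_per_patient):
                rec = synthesize_record(label, cfg, rng, patient_id=pid,
                                        patient_params=params)
                fname = f"{pid}_e{j}.png"
                try:
                    render_ecg_image(rec, cfg, path=out / fname)
                except OSError as exc:  # pragma: no cover - I/O context
                    raise OSError(f"failed writing {out / fname}: {exc}") from exc
                rows.append({"file": fname, "patient_id": pid, "label": label})
    manifest = pd.DataFrame(rows)
    assignment = _assign_patients(manifest["patient_id"], manifest["label"],
                                  cfg.split_ratio, cfg.seed)
    manifest["split"] = manifest["patient_id"].map(assignment)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
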