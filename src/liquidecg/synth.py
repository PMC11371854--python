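"""Seeded synthetic 12-lead ECG generator with class-conditioned morphology.

Each beat is a sum of Gaussian bumps (P, Q, R, S, T) projected onto the 12
leads through seeded per-bump projection vectors, so every lead carries a
different view of the same cardiac cycle. Label semantics follow the
standard clinical definitions of the six target abnormalities:

* SB   — sinus bradycardia: mean rate below 55 bpm (drawn 38-52);
* ST   — sinus tachycardia: mean rate above 110 bpm (drawn 115-150);
* AF   — atrial fibrillation: irregular RR intervals (coefficient of
         variation 0.18-0.30) with the P bump suppressed;
* 1dAVb — first-degree AV block: P-onset to QRS-onset (PR) interval above
         200 ms (drawn 240-320 ms);
* RBBB/LBBB — bundle branch block: QRS complex widened to >= 120 ms
         (drawn 130-160 ms) with lead-asymmetric amplitude boosts
         (right- vs left-facing leads);
* all-negative — rate 60-100 bpm, regular rhythm, normal PR and QRS.

Morphology is deliberately simplified: the target is class separability
with physiologically meaningful fiducials (which the generator records as
ground truth in each record's ``meta``), not clinical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import CLASSES, N_CLASSES, N_LEADS, Recording

_IDX = {name: i for i, name in enumerate(CLASSES)}

#: leads whose QRS amplitude a right bundle branch block accentuates (V1-V3)
_RBBB_LEADS = (6, 7, 8)
#: leads accentuated by a left bundle branch block (I, aVL, V5, V6)
_LBBB_LEADS = (0, 4, 10, 11)
_BBB_BOOST = 1.8

#: classes that may co-occur with a given primary label in sampled datasets
_COMPATIBLE = {
    "1dAVb": ("RBBB", "LBBB", "SB", "ST"),
    "RBBB": ("1dAVb", "SB", "ST", "AF"),
    "LBBB": ("1dAVb", "SB", "ST", "AF"),
    "SB": ("1dAVb", "RBBB", "LBBB"),
    "AF": ("RBBB", "LBBB"),
    "ST": ("1dAVb", "RBBB", "LBBB"),
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator conditions: cohort size, acquisition and morphology ranges."""

    n_records: int = 700
    fs: float = 400.0
    duration_s: float = 10.0
    #: per-class fraction of records whose primary label is that class;
    #: the remainder are all-negative records
    class_prevalences: tuple[float, ...] = (1 / 7,) * N_CLASSES
    multilabel_rate: float = 0.1
    noise_floor_std: float = 0.02
    baseline_wander_amp: float = 0.05
    seed: int = 0
    # beats per minute
    normal_rate: tuple[float, float] = (60.0, 100.0)
    sb_rate: tuple[float, float] = (38.0, 52.0)
    st_rate: tuple[float, float] = (115.0, 150.0)
    af_rate: tuple[float, float] = (75.0, 125.0)
    # seconds
    pr_normal: tuple[float, float] = (0.14, 0.18)
    pr_block: tuple[float, float] = (0.24, 0.32)
    qrs_normal: tuple[float, float] = (0.08, 0.10)
    qrs_wide: tuple[float, float] = (0.13, 0.16)
    # RR coefficient of variation
    rr_cv_normal: tuple[float, float] = (0.01, 0.04)
    rr_cv_af: tuple[float, float] = (0.20, 0.30)

    def __post_init__(self) -> None:
        if len(self.class_prevalences) != N_CLASSES:
            raise ValueError("class_prevalences must have six entries")
        if any(not 0 <= p <= 1 for p in self.class_prevalences):
            raise ValueError("prevalences must lie in [0,1]")
        if sum(self.class_prevalences) > 1 + 1e-9:
            raise ValueError("prevalences must sum to at most 1")
        if self.fs * self.duration_s < 1:
            raise ValueError("fs * duration must give at least one sample")


@dataclass
class MorphologyTemplate:
    """Per-bump amplitudes/widths and seeded 12-lead projection vectors."""

    amplitudes: dict[str, float]
    widths: dict[str, float]
    projections: dict[str, np.ndarray] = field(repr=False)

    @classmethod
    def default(cls, seed: int) -> "MorphologyTemplate":
        rng = np.random.default_rng(seed)
        bumps = ("P", "Q", "R", "S", "T")
        # random-but-seeded lead projections: each lead sees each bump with
        # its own gain (and occasionally inverted), so leads are informative
        # but not interchangeable
        projections = {}
        for b in bumps:
            gain = rng.uniform(0.5, 1.2, size=N_LEADS)
            sign = np.where(rng.random(N_LEADS) < 0.25, -1.0, 1.0)
            projections[b] = gain * sign
        return cls(
            amplitudes={"P": 0.18, "Q": -0.12, "R": 1.0, "S": -0.25, "T": 0.35},
            widths={"P": 0.022, "T": 0.06},  # Q/R/S widths scale with QRS duration
            projections=projections,
        )


def _gauss_add(sig: np.ndarray, t: np.ndarray, center: float, sigma: float,
               amps: np.ndarray) -> None:
    """Add a Gaussian bump (per-lead amplitudes) in place, windowed to 4 sigma."""
    lo = np.searchsorted(t, center - 4 * sigma)
    hi = np.searchsorted(t, center + 4 * sigma)
    if hi <= lo:
        return
    bump = np.exp(-0.5 * ((t[lo:hi] - center) / sigma) ** 2)
    sig[:, lo:hi] += amps[:, None] * bump[None, :]


def generate_record(
    cfg: SynthConfig,
    labels,
    seed: int,
    record_id: str = "",
    template: MorphologyTemplate | None = None,
) -> Recording:
    """One deterministic 12-lead recording conditioned on a 6-label vector."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (N_CLASSES,):
        raise ValueError("labels must be a 6-vector")
    lab = {name: bool(labels[_IDX[name]]) for name in CLASSES}
    if lab["SB"] and lab["ST"]:
        raise ValueError("contradictory labels: SB and ST are mutually exclusive")
    rng = np.random.default_rng(seed)
    tpl = template or MorphologyTemplate.default(cfg.seed)

    if lab["SB"]:
        rate = rng.uniform(*cfg.sb_rate)
    elif lab["ST"]:
        rate = rng.uniform(*cfg.st_rate)
    elif lab["AF"]:
        rate = rng.uniform(*cfg.af_rate)
    else:
        rate = rng.uniform(*cfg.normal_rate)
    rr_cv = rng.uniform(*(cfg.rr_cv_af if lab["AF"] else cfg.rr_cv_normal))
    pr = rng.uniform(*(cfg.pr_block if lab["1dAVb"] else cfg.pr_normal))
    qrs = rng.uniform(*(cfg.qrs_wide if lab["RBBB"] or lab["LBBB"] else cfg.qrs_normal))

    mean_rr = 60.0 / rate
    # gamma-shaped RR intervals, standardized so the realized coefficient of
    # variation matches the drawn target (a raw finite sample can fluctuate
    # below the AF irregularity threshold)
    n_beats = int(np.ceil(cfg.duration_s / mean_rr)) + 3
    shape_k = 1.0 / max(rr_cv, 1e-6) ** 2
    raw = rng.gamma(shape_k, mean_rr / shape_k, size=n_beats)
    dev = (raw - raw.mean()) / raw.std() if n_beats > 1 and raw.std() > 0 else raw * 0
    rr = np.clip(mean_rr * (1.0 + rr_cv * dev), 0.25 * mean_rr, None)
    start = rng.uniform(0.1, 0.3) + pr
    r_times = start + np.concatenate([[0.0], np.cumsum(rr)])

    qrs_proj = tpl.projections["R"].copy()
    boost = np.ones(N_LEADS)
    if lab["RBBB"]:
        boost[list(_RBBB_LEADS)] *= _BBB_BOOST
    if lab["LBBB"]:
        boost[list(_LBBB_LEADS)] *= _BBB_BOOST

    n = int(round(cfg.fs * cfg.duration_s))
    t = np.arange(n) / cfg.fs
    sig = np.zeros((N_LEADS, n))
    amp, wid, proj = tpl.amplitudes, tpl.widths, tpl.projections
    sigma_r = qrs / 7.0
    sigma_qs = qrs / 10.0
    p_sigma = wid["P"]
    for r_c in r_times:
        qrs_onset = r_c - qrs / 2
        if not lab["AF"]:
            p_center = qrs_onset - pr + 2 * p_sigma  # P onset precedes QRS onset by PR
            _gauss_add(sig, t, p_center, p_sigma, amp["P"] * proj["P"])
        _gauss_add(sig, t, r_c - qrs / 3, sigma_qs, amp["Q"] * proj["Q"] * boost)
        _gauss_add(sig, t, r_c, sigma_r, amp["R"] * qrs_proj * boost)
        _gauss_add(sig, t, r_c + qrs / 3, sigma_qs, amp["S"] * proj["S"] * boost)
        _gauss_add(sig, t, r_c + 0.25 + qrs, wid["T"], amp["T"] * proj["T"])

    # baseline wander + broadband noise floor
    f0 = rng.uniform(0.15, 0.4)
    phases = rng.uniform(0, 2 * np.pi, size=N_LEADS)
    sig += cfg.baseline_wander_amp * np.sin(2 * np.pi * f0 * t[None, :] + phases[:, None])
    sig += rng.normal(0.0, cfg.noise_floor_std, size=sig.shape)

    kept = r_times[r_times < cfg.duration_s]
    rr = np.diff(kept)
    fiducials = {
        "mean_rate_bpm": 60.0 / float(np.mean(rr)) if len(rr) else rate,
        "rr_cv": float(np.std(rr) / np.mean(rr)) if len(rr) > 1 else 0.0,
        "pr_s": float(pr),
        "qrs_s": float(qrs),
        "r_times_s": kept.tolist(),
        "has_p": not lab["AF"],
    }
    return Recording(
        signal=sig, fs=cfg.fs, labels=labels, record_id=record_id,
        meta={"fiducials": fiducials, "seed": int(seed)},
    )


def _allocate(n: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n records over groups."""
    raw = n * fractions
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def generate_dataset(cfg: SynthConfig | None = None) -> tuple[list[Recording], list[dict]]:
    """A labeled cohort plus a manifest of seeds and ground-truth fiducials.

    Records are grouped by primary class (six abnormalities + all-negative);
    with probability ``multilabel_rate`` a compatible secondary abnormality
    is added. Byte-identical for identical (config, seed).
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    template = MorphologyTemplate.default(cfg.seed)
    prevalences = np.asarray(cfg.class_prevalences, dtype=float)
    fractions = np.append(prevalences, max(0.0, 1.0 - prevalences.sum()))
    counts = _allocate(cfg.n_records, fractions)

    records: list[Recording] = []
    manifest: list[dict] = []
    i = 0
    for g, count in enumerate(counts):
        for _ in range(count):
            labels = np.zeros(N_CLASSES, dtype=int)
            if g < N_CLASSES:
                labels[g] = 1
                compat = _COMPATIBLE[CLASSES[g]]
                if compat and rng.random() < cfg.multilabel_rate:
                    labels[_IDX[str(rng.choice(compat))]] = 1
            seed = int(rng.integers(0, 2**31 - 1))
            rec = generate_record(
                cfg, labels, seed=seed, record_id=f"synth-{i:05d}", template=template
            )
            records.append(rec)
            manifest.append(
                {
                    "record_id": rec.record_id,
                    "seed": seed,
                    "labels": labels.tolist(),
                    "fiducials": rec.meta["fiducials"],
                }
            )
            i += 1
    return records, manifest
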