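"""Synthetic maternal-abdominal ECG mixtures with ground truth.

The generator emulates the structure of the FECGSYNDB-style simulated
corpus: a maternal ECG plus a lower-amplitude fetal ECG plus additive noise
at one of five SNR levels (0, 3, 6, 9, 12 dB), under physiological-event
scenarios:

* ``baseline`` — clean maternal + fetal mixture, no events;
* ``C0`` — baseline plus additive noise;
* ``C1`` — band-limited fetal amplitude modulation (fetal movement);
* ``C2`` — heart-rate acceleration/deceleration ramp (fetal or maternal);
* ``C3`` — a slow high-amplitude EMG-like burst (uterine contraction);
* ``C4`` — ectopic beats (swapped polarity, widened QRS) in both components;
* ``C5-stub`` — a second fetal component at a distinct rate (twin stub).

Each beat is the sum of five Gaussian waves (P, Q, R, S, T) whose centers
and widths are fractions of the local RR interval — an ECGSYN-style
time-domain model rather than a dipole simulation, which is enough to carry
the P/QRS/T morphology the extraction network must preserve.  All
randomness flows through one seeded generator per record, so records are
bit-reproducible from (spec, seed).

Noise SNR is defined against the *fetal* component:
``10*log10(P_fetal / P_noise) = noise_snr_db``, since the noise levels
stress fetal extraction.  The noise mixes white noise, a 0.3 Hz
baseline-wander drift and 50 Hz powerline interference, rescaled jointly so
the achieved SNR is exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .signal_io import Record, write_record

__all__ = [
    "BeatMorphology", "ScenarioSpec", "MATERNAL_MORPHOLOGY", "FETAL_MORPHOLOGY",
    "NOISE_LEVELS_DB", "SCENARIOS", "synth_single_ecg", "mix_abdominal",
    "apply_scenario_events", "make_scenario_record", "make_dataset",
    "scenario_grid",
]

NOISE_LEVELS_DB = (0.0, 3.0, 6.0, 9.0, 12.0)
SCENARIOS = ("baseline", "C0", "C1", "C2", "C3", "C4", "C5-stub")
_WAVES = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class BeatMorphology:
    """PQRST beat shape: five Gaussians in units of the local RR interval.

    ``wave_centers`` are phase offsets relative to the R peak (fraction of
    RR, P and Q negative), ``wave_amplitudes`` signed amplitudes in mV, and
    ``wave_widths`` Gaussian standard deviations (fraction of RR).
    """

    wave_centers: tuple[float, ...]
    wave_amplitudes: tuple[float, ...]
    wave_widths: tuple[float, ...]

    def __post_init__(self):
        c = np.asarray(self.wave_centers)
        a = np.asarray(self.wave_amplitudes)
        w = np.asarray(self.wave_widths)
        if not (len(c) == len(a) == len(w) == 5):
            raise ValueError("morphology needs exactly five waves (P,Q,R,S,T)")
        if np.any(w <= 0):
            raise ValueError("wave widths must be positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("wave centers must be ordered P < Q < R < S < T")
        if np.any(a) and np.argmax(np.abs(a)) != 2:
            raise ValueError("R amplitude must have the largest magnitude")

    def scaled(self, gain: float) -> "BeatMorphology":
        return replace(self, wave_amplitudes=tuple(
            gain * a for a in self.wave_amplitudes))

    def ectopic(self) -> "BeatMorphology":
        """Ectopic variant: swapped polarity and a widened QRS complex."""
        amps = tuple(-a for a in self.wave_amplitudes)
        widths = list(self.wave_widths)
        for i in (1, 2, 3):  # Q, R, S
            widths[i] *= 2.0
        return replace(self, wave_amplitudes=amps, wave_widths=tuple(widths))


# Maternal beats are wider (adult QRS ~80-100 ms); fetal beats share the
# shape but with a narrower QRS, per the usual abdominal-ECG description.
MATERNAL_MORPHOLOGY = BeatMorphology(
    wave_centers=(-0.25, -0.030, 0.0, 0.030, 0.30),
    wave_amplitudes=(0.12, -0.12, 1.10, -0.22, 0.28),
    wave_widths=(0.035, 0.010, 0.016, 0.012, 0.060),
)
FETAL_MORPHOLOGY = BeatMorphology(
    wave_centers=(-0.22, -0.025, 0.0, 0.025, 0.27),
    wave_amplitudes=(0.10, -0.10, 1.00, -0.18, 0.22),
    wave_widths=(0.030, 0.007, 0.009, 0.008, 0.050),
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Conditions for one synthetic record."""

    scenario: str = "C0"
    noise_snr_db: float | None = 6.0
    maternal_hr_bpm: float = 85.0
    fetal_hr_bpm: float = 140.0
    fm_amplitude_ratio: float = 0.25
    hr_modulation: dict | None = None  # {"target": "fetal", "hr_end_bpm": ...}
    ectopic_rate: float = 0.0  # ectopic beats per minute (both components)
    rr_jitter_pct: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (50 <= self.maternal_hr_bpm <= 140):
            raise ValueError("maternal heart rate outside 50-140 bpm")
        if not (100 <= self.fetal_hr_bpm <= 240):
            raise ValueError("fetal heart rate outside 100-240 bpm")
        if not (0 < self.fm_amplitude_ratio < 1):
            raise ValueError("fm_amplitude_ratio must be in (0, 1)")
        if self.noise_snr_db is not None and self.scenario != "baseline":
            if float(self.noise_snr_db) not in NOISE_LEVELS_DB:
                raise ValueError(
                    f"noise_snr_db must be one of {NOISE_LEVELS_DB} for "
                    f"scenario {self.scenario}"
                )


# ---------------------------------------------------------------------------
# beat-train rendering

def _render(beat_times, rrs, morphologies, fs, n) -> np.ndarray:
    """Render a beat train: sum of five Gaussians per beat."""
    t = np.arange(n) / fs
    sig = np.zeros(n)
    for t_r, rr, m in zip(beat_times, rrs, morphologies):
        lo = max(0, int((t_r - 0.6 * rr) * fs))
        hi = min(n, int((t_r + 0.8 * rr) * fs) + 1)
        if lo >= hi:
            continue
        tt = t[lo:hi]
        for c, a, w in zip(m.wave_centers, m.wave_amplitudes, m.wave_widths):
            sig[lo:hi] += a * np.exp(-0.5 * ((tt - t_r - c * rr) / (w * rr)) ** 2)
    return sig


def _beat_schedule(hr_start, hr_end, duration_s, jitter_pct, rng):
    """Beat times from an instantaneous-rate ramp with multiplicative jitter."""
    times, rrs, factors = [], [], []
    t = 0.5 * 60.0 / hr_start
    while t < duration_s:
        frac = min(t / duration_s, 1.0)
        hr = hr_start + (hr_end - hr_start) * frac
        f = max(1.0 + (jitter_pct / 100.0) * rng.standard_normal(), 0.5)
        rr = (60.0 / hr) * f
        times.append(t)
        rrs.append(rr)
        factors.append(f)
        t += rr
    return np.asarray(times), np.asarray(rrs), np.asarray(factors)


def _component_record(beat_times, rrs, morphologies, fs, n, role) -> Record:
    sig = _render(beat_times, rrs, morphologies, fs, n)
    peaks = np.round(np.asarray(beat_times) * fs).astype(int)
    peaks = peaks[(peaks >= 0) & (peaks < n)]
    kw = {"rpeaks_fetal": peaks} if role == "fetal_truth" else {"rpeaks_maternal": peaks}
    return Record(sig[None, :], fs, [role], **kw)


def synth_single_ecg(hr_bpm: float, duration_s: float, fs: float,
                     morphology: BeatMorphology, rr_jitter_pct: float = 0.0,
                     seed: int = 0, role: str = "fetal_truth") -> Record:
    """Generate a one-channel ECG of Gaussian PQRST beats.

    RR intervals are drawn around ``60/hr_bpm`` with multiplicative Gaussian
    jitter of ``rr_jitter_pct`` percent; the R-peak annotation holds the
    exact sample of each R-wave center.  Reproducible given ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs < 250:
        raise ValueError("fs must be at least 250 Hz")
    if not (50 <= hr_bpm <= 240):
        raise ValueError(f"heart rate {hr_bpm} bpm outside physiological range")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    times, rrs, factors = _beat_schedule(hr_bpm, hr_bpm, duration_s,
                                         rr_jitter_pct, rng)
    rec = _component_record(times, rrs, [morphology] * len(times), fs, n, role)
    rec.meta.update(
        gen={
            "hr_bpm": hr_bpm, "duration_s": duration_s,
            "jitter_factors": factors.tolist(),
            "morphology": asdict(morphology), "role": role,
        }
    )
    return rec


# ---------------------------------------------------------------------------
# scenario events

def _bandlimited_modulation(n, fs, rng, cutoff_hz=0.4, depth=0.35):
    """Smooth zero-mean modulation in [-depth, depth]."""
    from scipy.signal import butter, filtfilt

    raw = rng.standard_normal(n)
    b, a = butter(2, cutoff_hz / (fs / 2), btype="low")
    m = filtfilt(b, a, raw)
    m = m / (np.abs(m).max() + 1e-12) * depth
    return m


def _regenerate(record: Record, role: str, beat_times, rrs, morphologies) -> Record:
    comp = _component_record(beat_times, rrs, morphologies, record.fs,
                             record.n_samples, role)
    i = record.channel_roles.index(role)
    signals = record.signals.copy()
    signals[i] = comp.signals[0]
    kw = {"signals": signals}
    if role == "fetal_truth":
        kw["rpeaks_fetal"] = comp.rpeaks_fetal
    else:
        kw["rpeaks_maternal"] = comp.rpeaks_maternal
    return replace(record, **kw)


def apply_scenario_events(record: Record, spec: ScenarioSpec) -> Record:
    """Insert the scenario's physiological event into a mixed record.

    The record must hold ``maternal_truth`` and ``fetal_truth`` channels plus
    the generation metadata written by :func:`synth_single_ecg` (carried in
    ``meta['components']``).  The abdominal mixture and noise channels are
    left untouched; callers rebuild the mixture afterwards (see
    :func:`mix_abdominal`, which orchestrates the full chain).
    """
    if not (record.has_channel("fetal_truth") and record.has_channel("maternal_truth")):
        raise ValueError("record lacks truth channels")
    scen = spec.scenario
    if scen not in SCENARIOS:
        raise ValueError(f"unknown scenario token {scen!r}")
    if scen in ("baseline", "C0"):
        return record
    rng = np.random.default_rng((spec.seed * 0x9E3779B1 + 0xC2) % (2**31))
    comps = record.meta.get("components", {})

    if scen == "C1":
        i = record.channel_roles.index("fetal_truth")
        m = _bandlimited_modulation(record.n_samples, record.fs, rng)
        signals = record.signals.copy()
        signals[i] = signals[i] * (1.0 + m)
        return replace(record, signals=signals)

    if scen == "C2":
        mod = spec.hr_modulation or {"target": "fetal",
                                     "hr_end_bpm": spec.fetal_hr_bpm * 4 / 3}
        target = mod.get("target", "fetal")
        role = "fetal_truth" if target == "fetal" else "maternal_truth"
        hr0 = spec.fetal_hr_bpm if target == "fetal" else spec.maternal_hr_bpm
        hr1 = float(mod["hr_end_bpm"])
        comp = comps[role]
        duration = record.duration_s
        factors = np.asarray(comp["jitter_factors"])
        morph = BeatMorphology(**{k: tuple(v) for k, v in comp["morphology"].items()})
        # rebuild the schedule with the same jitter factors but ramped rate
        times, rrs = [], []
        t = 0.5 * 60.0 / hr0
        k = 0
        while t < duration:
            frac = min(t / duration, 1.0)
            hr = hr0 + (hr1 - hr0) * frac
            f = factors[k % len(factors)] if len(factors) else 1.0
            rr = (60.0 / hr) * f
            times.append(t)
            rrs.append(rr)
            t += rr
            k += 1
        return _regenerate(record, role, times, rrs, [morph] * len(times))

    if scen == "C3":
        # EMG-like uterine-contraction burst: band-limited noise under a
        # slow envelope, treated as interference (added to the noise budget
        # downstream, not to either truth channel).
        from scipy.signal import butter, filtfilt

        n, fs = record.n_samples, record.fs
        dur = min(10.0, record.duration_s / 3)
        center = rng.uniform(0.3, 0.7) * record.duration_s
        t = np.arange(n) / fs
        env = np.clip(1 - ((t - center) / (dur / 2)) ** 2, 0, None)
        b, a = butter(2, [3 / (fs / 2), 45 / (fs / 2)], btype="band")
        burst = filtfilt(b, a, rng.standard_normal(n)) * env
        m_peak = np.abs(record.channel("maternal_truth")).max()
        burst *= 1.2 * m_peak / (np.abs(burst).max() + 1e-12)
        meta = dict(record.meta)
        meta["event_interference"] = burst.tolist() if n <= 4096 else None
        meta.setdefault("events", []).append("uterine_contraction_burst")
        rec = replace(record, meta=meta)
        rec.meta["_burst"] = burst  # in-memory only; rebuilt by mix_abdominal
        return rec

    if scen == "C4":
        rate = spec.ectopic_rate if spec.ectopic_rate > 0 else 4.0
        out = record
        ectopic_meta = {}
        for role in ("fetal_truth", "maternal_truth"):
            comp = comps[role]
            morph = BeatMorphology(
                **{k: tuple(v) for k, v in comp["morphology"].items()})
            peaks = (out.rpeaks_fetal if role == "fetal_truth"
                     else out.rpeaks_maternal)
            times = peaks / out.fs
            rrs = np.full_like(times, 60.0 / spec.fetal_hr_bpm)
            if len(times) > 1:
                rrs[:-1] = np.diff(times)
                rrs[-1] = rrs[-2]
            # half the requested rate per component -> total matches the rate
            lam = (rate / 2.0) * out.duration_s / 60.0
            n_ect = min(rng.poisson(lam), len(times))
            idx = np.sort(rng.choice(len(times), size=n_ect, replace=False))
            morphs = [morph.ectopic() if i in set(idx.tolist()) else morph
                      for i in range(len(times))]
            out = _regenerate(out, role, times, rrs, morphs)
            ectopic_meta[role] = idx.tolist()
        meta = dict(out.meta)
        meta["ectopic_beats"] = ectopic_meta
        return replace(out, meta=meta)

    if scen == "C5-stub":
        twin_hr = min(spec.fetal_hr_bpm + 25.0, 240.0)
        twin = synth_single_ecg(twin_hr, record.duration_s, record.fs,
                                FETAL_MORPHOLOGY, spec.rr_jitter_pct,
                                seed=spec.seed + 7919, role="fetal_truth")
        i = record.channel_roles.index("fetal_truth")
        f_peak = np.abs(record.signals[i]).max()
        twin_sig = twin.signals[0] * 0.7 * f_peak / (np.abs(twin.signals[0]).max()
                                                     + 1e-12)
        signals = record.signals.copy()
        signals[i] = signals[i] + twin_sig
        meta = dict(record.meta)
        meta["rpeaks_fetal_twin"] = twin.rpeaks_fetal.tolist()
        return replace(record, signals=signals, meta=meta)

    raise ValueError(f"unhandled scenario {scen!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# mixing

def _calibrated_noise(n, fs, target_power, rng):
    """White + 0.3 Hz drift + 50 Hz powerline, jointly scaled to a power."""
    t = np.arange(n) / fs
    white = rng.standard_normal(n)
    drift = np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    mains = np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))

    def unit_power(x):
        return x / np.sqrt(np.mean(x**2) + 1e-300)

    raw = (np.sqrt(0.5) * unit_power(white)
           + np.sqrt(0.3) * unit_power(drift)
           + np.sqrt(0.2) * unit_power(mains))
    return raw * np.sqrt(target_power / np.mean(raw**2))


def mix_abdominal(mecg: Record, fecg: Record, spec: ScenarioSpec) -> Record:
    """Combine maternal and fetal ECGs into an annotated abdominal mixture.

    Chain: rescale the fetal component so the ratio of peak R amplitudes is
    ``spec.fm_amplitude_ratio``; apply the scenario event; add noise
    calibrated so ``10*log10(P_fetal / P_noise) = spec.noise_snr_db``.  The
    returned record holds channels ``[abdominal_mixture, maternal_truth,
    fetal_truth, noise]`` with both truth channels unmixed and both R-peak
    annotation sets carried through; the mixture always equals
    ``maternal_truth + fetal_truth + noise`` exactly.
    """
    if mecg.fs != fecg.fs or mecg.n_samples != fecg.n_samples:
        raise ValueError("maternal and fetal records must share fs and length")
    fs, n = mecg.fs, mecg.n_samples
    m_sig = mecg.channel("maternal_truth")
    f_sig = fecg.channel("fetal_truth")
    gain = spec.fm_amplitude_ratio * np.abs(m_sig).max() / (np.abs(f_sig).max()
                                                            + 1e-300)
    f_sig = f_sig * gain

    signals = np.vstack([m_sig + f_sig, m_sig, f_sig, np.zeros(n)])
    meta = {
        "scenario": spec.scenario,
        "noise_snr_db": spec.noise_snr_db,
        "seed": spec.seed,
        "components": {
            "maternal_truth": mecg.meta.get("gen"),
            "fetal_truth": fecg.meta.get("gen"),
        },
    }
    rec = Record(signals, fs,
                 ["abdominal_mixture", "maternal_truth", "fetal_truth", "noise"],
                 rpeaks_fetal=fecg.rpeaks_fetal,
                 rpeaks_maternal=mecg.rpeaks_maternal, meta=meta)

    rec = apply_scenario_events(rec, spec)
    burst = rec.meta.pop("_burst", None)

    i_mix, i_m, i_f, i_n = (rec.channel_roles.index(r) for r in
                            ("abdominal_mixture", "maternal_truth",
                             "fetal_truth", "noise"))
    signals = rec.signals.copy()
    noise = np.zeros(n)
    if spec.noise_snr_db is not None:
        p_f = float(np.mean(signals[i_f] ** 2))
        target = p_f / (10.0 ** (float(spec.noise_snr_db) / 10.0))
        rng = np.random.default_rng((spec.seed * 0x9E3779B1 + 0x17) % (2**31))
        noise = _calibrated_noise(n, fs, target, rng)
    if burst is not None:
        noise = noise + burst
    signals[i_n] = noise
    signals[i_mix] = signals[i_m] + signals[i_f] + noise
    return replace(rec, signals=signals)


def make_scenario_record(spec: ScenarioSpec, duration_s: float = 60.0,
                         fs: float = 250.0) -> Record:
    """Generate one complete synthetic abdominal record for a scenario."""
    mecg = synth_single_ecg(spec.maternal_hr_bpm, duration_s, fs,
                            MATERNAL_MORPHOLOGY, spec.rr_jitter_pct,
                            seed=spec.seed * 2 + 1, role="maternal_truth")
    fecg = synth_single_ecg(spec.fetal_hr_bpm, duration_s, fs,
                            FETAL_MORPHOLOGY, spec.rr_jitter_pct,
                            seed=spec.seed * 2 + 2, role="fetal_truth")
    return mix_abdominal(mecg, fecg, spec)


def scenario_grid(base_seed: int = 0) -> list[ScenarioSpec]:
    """The scenarios-by-noise-levels grid (7 x 5 = 35 combinations)."""
    grid = []
    for s_i, scen in enumerate(SCENARIOS):
        for n_i, snr in enumerate(NOISE_LEVELS_DB):
            grid.append(ScenarioSpec(scenario=scen, noise_snr_db=snr,
                                     seed=base_seed + 100 * s_i + n_i))
    return grid


def make_dataset(n_records: int, spec_grid: list[ScenarioSpec], out_dir,
                 duration_s: float = 60.0, fs: float = 250.0,
                 format: str = "csv") -> Path:
    """Write ``n_records`` records per spec plus a manifest table.

    Each record gets a distinct seed derived from its spec's seed and its
    replicate index, so the dataset is fully reproducible from the manifest.
    Returns the manifest path (tab-separated: path, scenario, noise, seed).
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in spec_grid:
        for rep in range(n_records):
            seed = spec.seed + 1000003 * rep
            rec_spec = replace(spec, seed=seed)
            rec = make_scenario_record(rec_spec, duration_s, fs)
            name = f"{spec.scenario.replace('-', '')}_snr{spec.noise_snr_db}_s{seed}"
            path = write_record(rec, out / name, format=format)
            rows.append((path.name, spec.scenario,
                         "" if spec.noise_snr_db is None else spec.noise_snr_db,
                         seed))
    manifest = out / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("path\tscenario\tnoise_snr_db\tseed\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")
    return manifest
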