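"""Synthetic two-group electrodermal activity cohorts with known ground truth.

Real subject recordings for this protocol are not publicly available, so
every downstream stage is exercised on simulated cohorts.  A recording is
built as

    signal = tonic trajectory + (SCR kernel * sparse event train) + noise

over five consecutive experimental phases (REST, MAT, REC1, RLX, REC2).
The tonic level is a group mean plus a smoothed Gaussian random walk plus a
stress-reactivity envelope that rises during the mental arithmetic task
(MAT) and relaxes back through the recovery phases.  Skin conductance
responses arrive as a homogeneous Poisson process per phase (the MAT rate
is multiplied by the group's reactivity gain) with log-normal amplitudes.
Group-level contrasts — lower tonic level, fewer non-specific SCRs and a
blunted task reactivity in the simulated patient group — mirror the
depression literature's reported electrodermal findings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, signal as sp_signal

from .decomp import biexponential_kernel
from .sigproc import EDARecording, PHASE_NAMES


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing of the five-phase recording protocol."""

    phase_names: tuple[str, ...] = PHASE_NAMES
    phase_duration_s: float = 300.0
    sampling_rate_hz: float = 256.0

    def __post_init__(self) -> None:
        if len(self.phase_names) != 5:
            raise ValueError("protocol requires exactly 5 phases")
        if self.phase_duration_s <= 0:
            raise ValueError("phase_duration_s must be > 0")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")

    @property
    def total_duration_s(self) -> float:
        return 5 * self.phase_duration_s

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_s * self.sampling_rate_hz))

    @property
    def phase_bounds(self) -> tuple[tuple[float, float], ...]:
        d = self.phase_duration_s
        return tuple((i * d, (i + 1) * d) for i in range(5))


@dataclass(frozen=True)
class GroupEffectSpec:
    """Group-level signal parameters of the generator.

    tonic_level_mean : mean skin conductance level, microsiemens.
    tonic_drift_sd   : SD of the tonic random walk per sqrt(second), uS.
    scr_rate_per_min : non-specific SCR rate outside the stress task.
    scr_amp_mean/sd  : mean / SD of the log-normal SCR amplitudes, uS.
    reactivity_gain  : multiplier on the MAT-phase SCR rate; also scales the
                       stress-induced tonic rise ((gain - 1) x 1 uS).
    noise_sd         : SD of the additive white Gaussian noise, uS.
    """

    tonic_level_mean: float = 6.0
    tonic_drift_sd: float = 0.02
    scr_rate_per_min: float = 3.0
    scr_amp_mean: float = 0.4
    scr_amp_sd: float = 0.2
    reactivity_gain: float = 2.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if min(self.tonic_drift_sd, self.scr_rate_per_min, self.scr_amp_sd, self.noise_sd) < 0:
            raise ValueError("rates and standard deviations must be >= 0")
        if self.scr_amp_mean <= 0:
            raise ValueError("scr_amp_mean must be > 0")
        if self.reactivity_gain < 0:
            raise ValueError("reactivity_gain must be >= 0")


def control_effects() -> GroupEffectSpec:
    """Default healthy-control generator settings."""
    return GroupEffectSpec()


def case_effects() -> GroupEffectSpec:
    """Default simulated-patient settings: lower tonic level, sparser
    non-specific SCRs and blunted stress reactivity."""
    return GroupEffectSpec(
        tonic_level_mean=4.0,
        scr_rate_per_min=1.5,
        scr_amp_mean=0.35,
        reactivity_gain=1.25,
    )


@dataclass
class GroundTruth:
    """Planted signal content of one synthetic recording: per-phase SCR event
    times (absolute seconds) and amplitudes (uS), and the true tonic curve."""

    events: dict[str, list[tuple[float, float]]]
    tonic: np.ndarray = field(repr=False)

    @property
    def all_events(self) -> list[tuple[float, float]]:
        out = [ev for phase in PHASE_NAMES for ev in self.events[phase]]
        return sorted(out)


def simulate_events(rate_per_min: float, duration_s: float, seed) -> np.ndarray:
    """Homogeneous Poisson event times on (0, duration_s), sorted.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if rate_per_min < 0:
        raise ValueError(f"rate_per_min must be >= 0, got {rate_per_min}")
    if duration_s <= 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = rng.poisson(rate_per_min * duration_s / 60.0)
    times = rng.uniform(np.nextafter(0.0, 1.0), duration_s, size=n)
    return np.sort(times)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _reactivity_envelope(protocol: ProtocolSpec, rise_tau_s: float = 15.0,
                         decay_tau_s: float = 60.0) -> np.ndarray:
    """Unit stress envelope: exponential rise over MAT, exponential relaxation
    from REC1 onward."""
    t = np.arange(protocol.n_samples) / protocol.sampling_rate_hz
    bounds = dict(zip(protocol.phase_names, protocol.phase_bounds))
    mat_start, mat_end = bounds["MAT"]
    env = np.zeros_like(t)
    in_mat = (t >= mat_start) & (t < mat_end)
    env[in_mat] = 1.0 - np.exp(-(t[in_mat] - mat_start) / rise_tau_s)
    level_at_end = 1.0 - np.exp(-(mat_end - mat_start) / rise_tau_s)
    after = t >= mat_end
    env[after] = level_at_end * np.exp(-(t[after] - mat_end) / decay_tau_s)
    return env


def synthesize_recording(
    protocol: ProtocolSpec,
    effects: GroupEffectSpec,
    seed: int,
    subject_id: str = "synthetic",
    group: str = "control",
) -> tuple[EDARecording, GroundTruth]:
    """Generate one recording plus its ground truth.

    With ``noise_sd = 0`` the signal equals tonic + kernel-convolved events
    exactly; conductance is clipped at zero from below (inactive at the
    default tonic levels).
    """
    rng = np.random.default_rng(seed)
    fs = protocol.sampling_rate_hz
    n = protocol.n_samples

    # Tonic: mean level + smoothed integrated Gaussian walk + stress envelope.
    dt = 1.0 / fs
    walk = np.cumsum(rng.normal(0.0, effects.tonic_drift_sd * np.sqrt(dt), size=n))
    walk = ndimage.gaussian_filter1d(walk, sigma=max(1.0, 2.0 * fs), mode="nearest")
    rise_uS = max(effects.reactivity_gain - 1.0, 0.0) * 1.0
    tonic = effects.tonic_level_mean + walk + rise_uS * _reactivity_envelope(protocol)

    # Phasic: per-phase Poisson events, MAT rate scaled by the reactivity gain.
    mu, sigma = _lognormal_params(effects.scr_amp_mean, effects.scr_amp_sd)
    driver = np.zeros(n)
    events: dict[str, list[tuple[float, float]]] = {}
    for name, (start, end) in zip(protocol.phase_names, protocol.phase_bounds):
        rate = effects.scr_rate_per_min * (effects.reactivity_gain if name == "MAT" else 1.0)
        times = simulate_events(rate, end - start, rng) + start
        amps = np.exp(rng.normal(mu, sigma, size=len(times)))
        events[name] = [(float(t), float(a)) for t, a in zip(times, amps)]
        idx = np.minimum((times * fs).round().astype(int), n - 1)
        np.add.at(driver, idx, amps)
    kernel = biexponential_kernel(0.7, 2.0, fs)
    phasic = sp_signal.fftconvolve(driver, kernel)[:n] if n > 0 else driver

    noise = rng.normal(0.0, effects.noise_sd, size=n) if effects.noise_sd > 0 else 0.0
    samples = np.clip(tonic + phasic + noise, 0.0, None)

    recording = EDARecording(
        subject_id=subject_id,
        group=group,
        sampling_rate_hz=fs,
        samples=samples,
        phase_bounds=protocol.phase_bounds,
        phase_names=protocol.phase_names,
    )
    return recording, GroundTruth(events=events, tonic=tonic)


def simulate_cohort(
    n_control: int,
    n_case: int,
    control_fx: GroupEffectSpec | None = None,
    case_fx: GroupEffectSpec | None = None,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
) -> list[tuple[EDARecording, GroundTruth]]:
    """Simulate a labelled cohort; subject ``i`` uses seed ``seed + i``.

    Controls come first (ids ``ctrl-XX``) then cases (``case-XX``).
    """
    if n_control < 1 or n_case < 1:
        raise ValueError("both groups need at least one subject")
    control_fx = control_fx or control_effects()
    case_fx = case_fx or case_effects()
    protocol = protocol or ProtocolSpec()
    cohort = []
    idx = 0
    for i in range(n_control):
        cohort.append(
            synthesize_recording(protocol, control_fx, seed + idx, f"ctrl-{i:02d}", "control")
        )
        idx += 1
    for i in range(n_case):
        cohort.append(
            synthesize_recording(protocol, case_fx, seed + idx, f"case-{i:02d}", "case")
        )
        idx += 1
    return cohort


# ---------------------------------------------------------------------------
# On-disk dialect: CSV (time_s, eda_uS) + JSON sidecar + ground-truth JSON.

def write_recording(rec: EDARecording, directory: str | Path,
                    truth: GroundTruth | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(len(rec.samples)) / rec.sampling_rate_hz
    csv_path = directory / f"{rec.subject_id}.csv"
    np.savetxt(
        csv_path,
        np.column_stack([t, rec.samples]),
        delimiter=",",
        header="time_s,eda_uS",
        comments="",
        fmt="%.6f",
    )
    sidecar = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "phase_names": list(rec.phase_names),
        "phase_bounds": [list(b) for b in rec.phase_bounds],
    }
    (directory / f"{rec.subject_id}.json").write_text(json.dumps(sidecar, indent=1))
    if truth is not None:
        gt = {"events": truth.events, "tonic_mean_uS": float(np.mean(truth.tonic))}
        (directory / f"{rec.subject_id}.truth.json").write_text(json.dumps(gt, indent=1))
    return csv_path


def read_recording(csv_path: str | Path) -> EDARecording:
    csv_path = Path(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    return EDARecording(
        subject_id=sidecar["subject_id"],
        group=sidecar["group"],
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        samples=data[:, 1],
        phase_bounds=tuple(tuple(b) for b in sidecar["phase_bounds"]),
        phase_names=tuple(sidecar["phase_names"]),
    )


def protocol_to_dict(protocol: ProtocolSpec) -> dict:
    return asdict(protocol) | {"phase_names": list(protocol.phase_names)}
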