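"""Per-phase analysis windows and the 36 electrodermal features.

From each of the five phases (primary sets P1..P5) a 150-second analysis
window yields four features of the decomposed signal: MSCL, SDSCL and SKSCL
(mean, sample SD and skewness of the tonic skin conductance level) and
NSSCR (the count of non-specific skin conductance responses detected on
the phasic component).  The window sits at the start of the stress task
(MAT, to capture activation before habituation) and at the end of every
other phase (to capture settled baseline or recovered activity).

Four derived sets difference the primary features between phase pairs:
D1 = MAT - REST (stress reactivity), D2 = REC1 - REST (before/after
stress), D3 = REC1 - RLX (relaxation reactivity), D4 = REC1 - REC2
(before/after relaxation) — 16 differential features, 36 in total.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import decomp
from .sigproc import EDARecording, PHASE_NAMES

#: primary set label -> protocol phase
PRIMARY_SETS: dict[str, str] = {
    "P1": "REST",
    "P2": "MAT",
    "P3": "REC1",
    "P4": "RLX",
    "P5": "REC2",
}

#: derived set label -> (minuend phase, subtrahend phase)
DERIVED_PAIRS: dict[str, tuple[str, str]] = {
    "D1": ("MAT", "REST"),
    "D2": ("REC1", "REST"),
    "D3": ("REC1", "RLX"),
    "D4": ("REC1", "REC2"),
}

BASE_FEATURES = ("MSCL", "SDSCL", "SKSCL", "NSSCR")

FEATURE_COLUMNS: tuple[str, ...] = tuple(
    [f"{p}_{f}" for p in PRIMARY_SETS for f in BASE_FEATURES]
    + [f"{d}_d{f}" for d in DERIVED_PAIRS for f in BASE_FEATURES]
)


@dataclass(frozen=True)
class ScrParams:
    """Detection criterion for non-specific SCRs on the phasic component."""

    min_amp_uS: float = 0.05
    min_separation_s: float = 1.0


@dataclass(frozen=True)
class WindowPolicy:
    """Analysis-window length and per-phase placement (first or last)."""

    window_length_s: float = 150.0
    placement: dict[str, str] = field(
        default_factory=lambda: {
            "REST": "last",
            "MAT": "first",
            "REC1": "last",
            "RLX": "last",
            "REC2": "last",
        }
    )

    def __post_init__(self) -> None:
        if self.window_length_s <= 0:
            raise ValueError("window_length_s must be > 0")
        missing = set(PHASE_NAMES) - set(self.placement)
        if missing:
            raise ValueError(f"placement missing for phases: {sorted(missing)}")
        bad = set(self.placement.values()) - {"first", "last"}
        if bad:
            raise ValueError(f"placement must be 'first' or 'last', got {sorted(bad)}")


def select_window(
    phase_bounds: tuple[float, float], placement: str, window_s: float, rate_hz: float
) -> tuple[int, int]:
    """Half-open sample interval of the analysis window inside one phase."""
    start_s, end_s = phase_bounds
    if window_s > end_s - start_s + 1e-9:
        raise ValueError(
            f"window of {window_s}s does not fit in phase [{start_s}, {end_s})s"
        )
    if placement == "first":
        lo, hi = start_s, start_s + window_s
    elif placement == "last":
        lo, hi = end_s - window_s, end_s
    else:
        raise ValueError(f"placement must be 'first' or 'last', got {placement!r}")
    return int(round(lo * rate_hz)), int(round(hi * rate_hz))


def compute_primary(
    tonic: np.ndarray,
    phasic: np.ndarray,
    window: tuple[int, int],
    rate_hz: float,
    scr_params: ScrParams = ScrParams(),
) -> dict[str, float]:
    """MSCL / SDSCL / SKSCL on the tonic component and NSSCR on the phasic
    component, inside one analysis window.

    SDSCL is the n-1 sample standard deviation; SKSCL is the uncorrected
    Fisher-Pearson skewness g1, defined as 0 on a zero-variance window.
    NSSCR counts detected SCR peaks whose peak time falls in the window.
    """
    i0, i1 = window
    if i0 < 0 or i1 > len(tonic) or i1 <= i0:
        raise ValueError(f"window [{i0}, {i1}) outside series of length {len(tonic)}")
    seg = np.asarray(tonic[i0:i1], dtype=float)
    mscl = float(seg.mean())
    sdscl = float(seg.std(ddof=1)) if len(seg) > 1 else 0.0
    skscl = float(stats.skew(seg, bias=True)) if sdscl > 0 else 0.0
    events = decomp.detect_scr_peaks(
        phasic, rate_hz, scr_params.min_amp_uS, scr_params.min_separation_s
    )
    t0, t1 = i0 / rate_hz, i1 / rate_hz
    nsscr = sum(1 for t, _ in events if t0 <= t < t1)
    return {"MSCL": mscl, "SDSCL": sdscl, "SKSCL": skscl, "NSSCR": float(nsscr)}


def compute_derived(primary: dict[str, dict[str, float]]) -> dict[str, float]:
    """The 16 differential features from the four documented phase pairs."""
    out: dict[str, float] = {}
    for dset, (minuend, subtrahend) in DERIVED_PAIRS.items():
        for feat in BASE_FEATURES:
            out[f"{dset}_d{feat}"] = primary[minuend][feat] - primary[subtrahend][feat]
    return out


def subject_features(
    recording: EDARecording,
    result: decomp.DecompositionResult,
    policy: WindowPolicy = WindowPolicy(),
    scr_params: ScrParams = ScrParams(),
) -> dict[str, float]:
    """All 36 features of one decomposed recording, keyed by column name."""
    rate = result.rate_hz
    per_phase: dict[str, dict[str, float]] = {}
    for name, bounds in zip(recording.phase_names, recording.phase_bounds):
        window = select_window(bounds, policy.placement[name], policy.window_length_s, rate)
        per_phase[name] = compute_primary(
            result.tonic, result.phasic, window, rate, scr_params
        )
    row: dict[str, float] = {}
    for pset, phase in PRIMARY_SETS.items():
        for feat in BASE_FEATURES:
            row[f"{pset}_{feat}"] = per_phase[phase][feat]
    row.update(compute_derived(per_phase))
    return row


def assemble_feature_table(
    decompositions: list[tuple[EDARecording, decomp.DecompositionResult]],
    policy: WindowPolicy = WindowPolicy(),
    scr_params: ScrParams = ScrParams(),
) -> pd.DataFrame:
    """One row per subject: subject_id, group, then the 36 features in the
    fixed documented order (P1..P5 x base features, then D1..D4)."""
    rows = []
    for recording, result in decompositions:
        row = {"subject_id": recording.subject_id, "group": recording.group}
        row.update(subject_features(recording, result, policy, scr_params))
        rows.append(row)
    table = pd.DataFrame(rows, columns=["subject_id", "group", *FEATURE_COLUMNS])
    return table


def _header_checksum(columns) -> str:
    return hashlib.sha256(",".join(columns).encode()).hexdigest()[:16]


def write_feature_table(table: pd.DataFrame, path: str | Path, meta: str = "") -> None:
    """CSV with a leading comment line carrying a header checksum (and any
    caller-supplied metadata such as a config hash)."""
    path = Path(path)
    buf = StringIO()
    table.to_csv(buf, index=False, lineterminator="\n")
    line = f"# header_sha256={_header_checksum(table.columns)}"
    if meta:
        line += f" {meta}"
    path.write_text(line + "\n" + buf.getvalue())


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        table = pd.read_csv(fh)
    expected = first.split("header_sha256=")[1].split()[0]
    if _header_checksum(table.columns) != expected:
        raise ValueError(f"feature-table header checksum mismatch in {path}")
    return table
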