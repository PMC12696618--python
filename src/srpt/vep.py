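"""Event-aligned epoching, trial averaging, and VEP measurement.

Conventions
-----------
* Times are milliseconds; within an epoch, 0 is the onset of the alignment
  (sequence-initial) stimulus and sample windows are half-open ``[start, end)``.
* Latency is the time of the minimum-voltage sample in a search window
  (the maximal negative-going peak); ties break toward the earliest sample.
* Magnitude is peak-to-peak: the maximum voltage *after* the negative peak
  (through the window end) minus the minimum.
* The N2 positivity is the post-trough maximum minus the voltage at the
  onset of the driving stimulus, so it is invariant to DC offsets.
* No baseline subtraction is applied to measures; windows that cannot be
  quantified (flat signal, extremum on the window edge) propagate as NaN
  with ``valid=False``, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .protocols import SessionProtocol, StimulusEvent
from .simulate import CohortDataset, LfpRecording

__all__ = [
    "TrialMatrix",
    "Vep",
    "ComponentSpec",
    "ComponentMeasure",
    "extract_epochs",
    "average_vep",
    "vep_latency",
    "vep_magnitude",
    "component_measures",
    "a2_positivity",
    "sequence_magnitude",
    "block_latencies",
    "average_hemispheres",
    "plasticity_delta",
    "detect_biphasic",
    "default_component_specs",
    "quantify_recording",
    "quantify_cohort",
]


@dataclass
class TrialMatrix:
    """Trials x samples voltage matrix aligned to one event class."""

    values: np.ndarray              # (n_trials, n_samples), microvolts
    window: tuple[float, float]     # ms relative to alignment onset
    sample_rate: float
    alignment_role: str = ""

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.values.shape[1]
        return self.window[0] + np.arange(n) * 1000.0 / self.sample_rate


@dataclass
class Vep:
    """Trial-averaged evoked potential."""

    waveform: np.ndarray
    window: tuple[float, float]
    sample_rate: float
    n_trials: int
    channel: str = ""

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(len(self.waveform)) * 1000.0 / self.sample_rate


@dataclass(frozen=True)
class ComponentSpec:
    """Search window for one named VEP component.

    ``search_window`` is relative to the onset of the component's driving
    stimulus; ``driving_position`` locates that stimulus within the sequence
    so windows can be mapped into the epoch's (sequence-aligned) time base.
    """

    name: str
    search_window: tuple[float, float]
    driving_role: str = "A"
    driving_position: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.search_window
        if lo >= hi:
            raise ValueError("search window must satisfy lo < hi")

    def epoch_window(self, stimulus_duration: float) -> tuple[float, float]:
        off = (self.driving_position - 1) * stimulus_duration
        lo, hi = self.search_window
        return (off + lo, off + hi)


@dataclass
class ComponentMeasure:
    """Latency / magnitude / positivity for one component, NaN when invalid."""

    name: str
    latency: float                 # ms relative to the driving-stimulus onset
    magnitude: float               # microvolts, peak-to-peak
    positivity: float | None = None
    n_trials: int = 0
    day: int = 0
    condition: str = ""
    valid: bool = True
    latency_from_lead: float = np.nan  # auxiliary: relative to sequence onset


def extract_epochs(
    recording: LfpRecording,
    events: list[StimulusEvent],
    window: tuple[float, float],
    channel: str,
) -> TrialMatrix:
    """Slice the continuous record around each event onset.

    Row *i* is the voltage aligned to ``events[i]``; event order is preserved.
    Raises if any epoch extends beyond the recording.
    """
    if not events:
        raise ValueError("empty event selection")
    v = recording.voltage[channel]
    rate = recording.sample_rate
    s0 = int(round(window[0] * rate / 1000.0))
    s1 = int(round(window[1] * rate / 1000.0))
    if s1 <= s0:
        raise ValueError("window must have positive length")
    onsets = np.array(
        [int(round((ev.onset - recording.t0_ms) * rate / 1000.0)) for ev in events]
    )
    if (onsets + s0 < 0).any() or (onsets + s1 > len(v)).any():
        raise ValueError("epoch exceeds recording bounds")
    idx = onsets[:, None] + np.arange(s0, s1)[None, :]
    return TrialMatrix(
        values=v[idx].astype(float),
        window=window,
        sample_rate=rate,
        alignment_role=events[0].role,
    )


def average_vep(
    matrix: TrialMatrix, trial_subset: np.ndarray | list[int] | None = None,
    channel: str = "",
) -> Vep:
    """Pointwise arithmetic mean over (a subset of) trials."""
    if trial_subset is None:
        rows = matrix.values
    else:
        trial_subset = np.asarray(trial_subset)
        if trial_subset.size == 0:
            raise ValueError("empty trial subset")
        rows = matrix.values[trial_subset]
    return Vep(
        waveform=rows.mean(axis=0),
        window=matrix.window,
        sample_rate=matrix.sample_rate,
        n_trials=rows.shape[0],
        channel=channel,
    )


def _window_slice(vep: Vep, search_window: tuple[float, float]) -> tuple[int, int]:
    lo, hi = search_window
    if lo < vep.window[0] - 1e-9 or hi > vep.window[1] + 1e-9:
        raise ValueError("search window outside the epoch window")
    rate = vep.sample_rate
    i0 = int(round((lo - vep.window[0]) * rate / 1000.0))
    i1 = int(round((hi - vep.window[0]) * rate / 1000.0))
    if i1 <= i0:
        raise ValueError("empty search window")
    return i0, i1


def vep_latency(vep: Vep, search_window: tuple[float, float]) -> float:
    """Time (ms, epoch time base) of the maximal negative-going peak.

    Returns NaN when the window is flat (no peak to quantify).
    """
    i0, i1 = _window_slice(vep, search_window)
    seg = vep.waveform[i0:i1]
    if np.ptp(seg) == 0:
        return float("nan")
    imin = int(np.argmin(seg))  # argmin takes the earliest of tied minima
    return vep.window[0] + (i0 + imin) * 1000.0 / vep.sample_rate


def vep_magnitude(vep: Vep, search_window: tuple[float, float]) -> float:
    """Peak-to-peak voltage: post-trough maximum minus the trough.

    The positivity is searched only after the negative peak; if the trough
    falls on the final sample there is no room for a positivity and the
    measure is flagged NaN.
    """
    i0, i1 = _window_slice(vep, search_window)
    seg = vep.waveform[i0:i1]
    if np.ptp(seg) == 0:
        return float("nan")
    imin = int(np.argmin(seg))
    if imin == len(seg) - 1:
        return float("nan")
    return float(seg[imin:].max() - seg[imin])


def a2_positivity(vep: Vep, a2_spec: ComponentSpec, stimulus_duration: float = 300.0) -> float:
    """Positive deflection after the N2 trough, relative to voltage at onset 0.

    The epoch must include the sequence-onset sample (time 0).  NaN when the
    N2 itself is unquantifiable.
    """
    if vep.window[0] > 0 or vep.window[1] <= 0:
        raise ValueError("epoch must include the stimulus-onset sample")
    win = a2_spec.epoch_window(stimulus_duration)
    lat = vep_latency(vep, win)
    if np.isnan(lat):
        return float("nan")
    rate = vep.sample_rate
    i_onset = int(round((0.0 - vep.window[0]) * rate / 1000.0))
    i_tr = int(round((lat - vep.window[0]) * rate / 1000.0))
    i_end = int(round((win[1] - vep.window[0]) * rate / 1000.0))
    if i_tr >= i_end:
        return float("nan")
    return float(vep.waveform[i_tr:i_end].max() - vep.waveform[i_onset])


def component_measures(
    vep: Vep,
    specs: list[ComponentSpec],
    stimulus_duration: float,
) -> list[ComponentMeasure]:
    """Measure latency and magnitude for each component spec.

    Component latencies are reported relative to the onset of each
    component's own driving stimulus; ``latency_from_lead`` keeps the
    sequence-onset-referenced value for cross-convention comparisons.
    Windows of distinct components may not overlap within the epoch.
    """
    windows = sorted(spec.epoch_window(stimulus_duration) for spec in specs)
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if b0 < a1:
            raise ValueError("component search windows overlap")
    out = []
    for spec in specs:
        win = spec.epoch_window(stimulus_duration)
        off = (spec.driving_position - 1) * stimulus_duration
        lat_abs = vep_latency(vep, win)
        mag = vep_magnitude(vep, win)
        valid = not (np.isnan(lat_abs) or np.isnan(mag))
        out.append(
            ComponentMeasure(
                name=spec.name,
                latency=lat_abs - off,
                magnitude=mag,
                n_trials=vep.n_trials,
                valid=valid,
                latency_from_lead=lat_abs,
            )
        )
    return out


def sequence_magnitude(magnitudes) -> float:
    """Mean of the four per-element VEP magnitudes, (A + B + C + D) / 4."""
    mags = [float(m) for m in magnitudes]
    if len(mags) != 4:
        raise ValueError("sequence magnitude requires exactly four values")
    if any(np.isnan(m) for m in mags):
        raise ValueError("missing component magnitude")
    return float(np.mean(mags))


def block_latencies(
    matrix: TrialMatrix,
    search_window: tuple[float, float],
    block_size: int = 50,
) -> list[tuple[int, float]]:
    """Latency per contiguous trial block (within-session plasticity probe)."""
    n = matrix.n_trials
    if block_size <= 0 or n % block_size:
        raise ValueError("trial count must divide evenly into blocks")
    out = []
    for b in range(n // block_size):
        rows = np.arange(b * block_size, (b + 1) * block_size)
        vep = average_vep(matrix, rows)
        out.append((b + 1, vep_latency(vep, search_window)))
    return out


def average_hemispheres(
    left: ComponentMeasure, right: ComponentMeasure
) -> ComponentMeasure:
    """Average bilateral measures; fall back to the single valid hemisphere."""
    if (left.name, left.day, left.condition) != (right.name, right.day, right.condition):
        raise ValueError("hemisphere measures must share name/day/condition")
    if not left.valid and not right.valid:
        raise ValueError("both hemispheres invalid")
    if left.valid and right.valid:
        pos = None
        if left.positivity is not None and right.positivity is not None:
            pos = 0.5 * (left.positivity + right.positivity)
        return replace(
            left,
            latency=0.5 * (left.latency + right.latency),
            magnitude=0.5 * (left.magnitude + right.magnitude),
            positivity=pos,
            latency_from_lead=0.5 * (left.latency_from_lead + right.latency_from_lead),
            n_trials=left.n_trials,
        )
    return left if left.valid else right


def plasticity_delta(day1_latency: float, day4_latency: float) -> float:
    """Day 4 minus Day 1 latency (negative = response speeding)."""
    if np.isnan(day1_latency) or np.isnan(day4_latency):
        raise ValueError("plasticity delta requires two quantifiable latencies")
    return float(day4_latency - day1_latency)


def detect_biphasic(
    vep: Vep,
    window: tuple[float, float],
    depth_fraction: float = 0.5,
    min_separation_ms: float = 15.0,
    prominence_fraction: float = 0.25,
) -> tuple[bool, list[float]]:
    """Detect a two-trough (composite) response in a search window.

    True iff at least two local minima are each deeper than
    ``depth_fraction`` times the global minimum and separated by at least
    ``min_separation_ms``.  Returns the trough times found.  Flat input is
    simply not biphasic (no error).
    """
    i0, i1 = _window_slice(vep, window)
    seg = vep.waveform[i0:i1]
    depth = -seg.min()
    if depth <= 0:
        return False, []
    dist = max(1, int(round(min_separation_ms * vep.sample_rate / 1000.0)))
    peaks, _ = find_peaks(
        -seg,
        height=depth_fraction * depth,
        distance=dist,
        prominence=prominence_fraction * depth,
    )
    times = [
        vep.window[0] + (i0 + int(p)) * 1000.0 / vep.sample_rate for p in peaks
    ]
    return len(times) >= 2, times


# ---------------------------------------------------------------------------
# default component windows and tidy-measure pipeline
# ---------------------------------------------------------------------------

#: ACC search windows (ms, relative to the driving stimulus onset)
ACC_N1_WINDOW = (20.0, 120.0)
ACC_N2_WINDOW = (120.0, 320.0)
#: V1 window covering the fast N1 and its positivity
V1_WINDOW = (20.0, 200.0)


def default_component_specs(
    kind: str,
    stimulus_duration: float,
    channel: str = "ACC",
    lead_role: str | None = None,
) -> list[ComponentSpec]:
    """Component specs for one protocol kind / duration / region.

    ACC, sequence-initial stimulus: N1 at 20-120 ms and N2 at 120-320 ms
    post-onset (N2 capped at the next stimulus onset + 20 ms when stimuli
    are shorter than 300 ms, where N2 and the next N1 are not separable).
    Follow-up stimuli contribute their own-onset N1 windows.  V1 uses a
    single 20-200 ms window per stimulus.
    """
    lead_names = {"A": ("A1", "A2"), "N": ("N1", "N2"), "D": ("D1", "D2")}
    seq_roles = {
        "ABCD": ["A", "B", "C", "D"],
        "DCBA": ["D", "C", "B", "A"],
        "AXXX": ["A", "X", "X", "X"],
        "NXXX": ["N", "X", "X", "X"],
        "SINGLE": [lead_role or "A"],
        "PHASE_REVERSAL": ["REVERSAL"],
    }[kind]
    specs: list[ComponentSpec] = []
    if channel.startswith("V1"):
        for pos, role in enumerate(seq_roles, start=1):
            specs.append(
                ComponentSpec(
                    name=f"{role}{pos}" if role == "X" else role,
                    search_window=V1_WINDOW
                    if stimulus_duration >= 200
                    else (20.0, stimulus_duration),
                    driving_role=role,
                    driving_position=pos,
                )
            )
        return specs

    lead = seq_roles[0]
    n1_name, n2_name = lead_names.get(lead, (f"{lead}1", f"{lead}2"))
    specs.append(
        ComponentSpec(name=n1_name, search_window=ACC_N1_WINDOW,
                      driving_role=lead, driving_position=1)
    )
    if stimulus_duration >= 300 or len(seq_roles) == 1:
        n2_hi = ACC_N2_WINDOW[1]
        if len(seq_roles) > 1:
            n2_hi = min(n2_hi, stimulus_duration + 20.0)
        specs.append(
            ComponentSpec(name=n2_name, search_window=(ACC_N2_WINDOW[0], n2_hi),
                          driving_role=lead, driving_position=1)
        )
        for pos, role in enumerate(seq_roles[1:], start=2):
            if role == "X" and pos > 2:
                continue  # only the first pseudorandom follow-up is analyzed
            name = f"{role}1"
            lo = 20.0 if pos > 2 else max(20.0, n2_hi - stimulus_duration)
            specs.append(
                ComponentSpec(name=name, search_window=(lo, 120.0),
                              driving_role=role, driving_position=pos)
            )
    else:
        # short stimuli: N2 and the next N1 overlap; a single composite
        # window spanning both is all that can be measured
        specs.append(
            ComponentSpec(
                name="B-composite",
                search_window=(20.0, 120.0),
                driving_role=seq_roles[1],
                driving_position=2,
            )
        )
    return specs


def _component_class(spec: ComponentSpec, channel: str) -> str:
    """Position-based component class, stable across lead-role nomenclature."""
    if channel.startswith("V1"):
        return "v1"
    if spec.name == "B-composite":
        return "composite"
    if spec.driving_position == 1:
        return "lead-N2" if spec.name.endswith("2") else "lead-N1"
    return "follow-N1"


def _prestim_noise_sd(vep: Vep) -> float:
    """SD of the average waveform before stimulus onset (validity reference)."""
    if vep.window[0] >= 0:
        return float("nan")
    i_end = int(round((0.0 - vep.window[0]) * vep.sample_rate / 1000.0))
    return float(np.std(vep.waveform[:i_end]))


def quantify_recording(
    recording: LfpRecording,
    protocol: SessionProtocol | None = None,
    channels: list[str] | None = None,
    epoch_pre_ms: float = 100.0,
    epoch_post_pad_ms: float = 420.0,
    min_trials: int = 50,
    snr_validity_factor: float = 3.0,
) -> pd.DataFrame:
    """All component measures for one session, as a tidy table.

    Epochs are aligned to sequence-initial events.  A channel's VEP is
    flagged invalid when its peak-to-peak amplitude is below
    ``snr_validity_factor`` times the pre-stimulus noise SD of the average,
    or when fewer than ``min_trials`` trials contribute.
    """
    if protocol is None:
        protocol = recording.events
    if protocol is None:
        raise ValueError("no event protocol attached to the recording")
    if channels is None:
        channels = recording.channels
    dur = protocol.stimulus_duration
    seq_len = max(ev.seq_position for ev in protocol.events)
    window = (-epoch_pre_ms, seq_len * dur + epoch_post_pad_ms)
    leads = protocol.select(seq_position=1)
    rows = []
    for ch in channels:
        specs = default_component_specs(
            protocol.kind, dur, channel=ch, lead_role=protocol.lead_role
        )
        matrix = extract_epochs(recording, leads, window, channel=ch)
        vep = average_vep(matrix, channel=ch)
        noise_sd = _prestim_noise_sd(vep)
        low_n = vep.n_trials < min_trials
        for spec, meas in zip(specs, component_measures(vep, specs, dur)):
            pos = None
            if spec.name.endswith("2") and spec.driving_position == 1:
                pos = a2_positivity(vep, spec, dur)
            ptp_ok = (
                not np.isfinite(noise_sd)
                or not meas.valid
                or meas.magnitude >= snr_validity_factor * noise_sd
            )
            valid = meas.valid and ptp_ok and not low_n
            rows.append(
                dict(
                    channel=ch,
                    component=spec.name,
                    component_class=_component_class(spec, ch),
                    latency_ms=meas.latency,
                    latency_from_lead_ms=meas.latency_from_lead,
                    magnitude_uv=meas.magnitude,
                    positivity_uv=pos if pos is not None else np.nan,
                    n_trials=vep.n_trials,
                    valid=valid,
                )
            )
    return pd.DataFrame(rows)


def _merge_hemispheres(df: pd.DataFrame) -> pd.DataFrame:
    """Average V1L/V1R rows into synthetic 'V1' rows (valid-only mean)."""
    v1 = df[df["channel"].str.startswith("V1")]
    if v1.empty:
        return df
    merged = []
    value_cols = ["latency_ms", "latency_from_lead_ms", "magnitude_uv", "positivity_uv"]
    for comp, grp in v1.groupby("component", sort=False):
        ok = grp[grp["valid"]]
        if ok.empty:
            continue
        row = ok.iloc[0].copy()
        row["channel"] = "V1"
        for c in value_cols:
            row[c] = ok[c].mean()
        row["valid"] = True
        merged.append(row)
    if not merged:
        return df
    return pd.concat([df, pd.DataFrame(merged)], ignore_index=True)


def quantify_cohort(
    cohort: CohortDataset,
    channels: list[str] | None = None,
    merge_hemispheres: bool = True,
) -> pd.DataFrame:
    """Tidy measures for every session of a cohort.

    Columns: subject, genotype, day, channel, condition, component,
    latency_ms, magnitude_uv, positivity_uv, n_trials, valid (plus the
    auxiliary sequence-onset-referenced latency).  V1 hemispheres are
    averaged into additional ``channel == "V1"`` rows.
    """
    frames = []
    for rec, protocol, recording in cohort.iter_sessions(channels=channels):
        df = quantify_recording(recording, protocol, channels=channels)
        if merge_hemispheres:
            df = _merge_hemispheres(df)
        df.insert(0, "subject", rec.subject_id)
        df.insert(1, "genotype", rec.genotype)
        df.insert(2, "day", rec.day)
        df.insert(3, "condition", rec.condition)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
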