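"""Synthetic continuous-LFP generator with known ground truth.

The forward model is deliberately simple: every stimulus presentation adds a
stereotyped evoked kernel (a sum of truncated Gaussian lobes) to the ongoing
voltage, on top of white plus 1/f ("pink") background noise.  Sequence-initial
stimuli additionally drive a slow second negativity (the N2 / "A2" component)
and its trailing positivity; within-sequence stimuli drive only a fast N1.
Familiarity-driven plasticity is programmed as day-indexed schedules:

* wild-type (WT) ACC: the N2 negative-lobe latency of the familiar
  orientation shortens across days (fully expressed by Day 2);
* the Angelman-syndrome model regime (AS): no latency shift, but the N2
  positivity amplitude grows across days;
* V1: all kernel amplitudes for trained orientations scale up across days
  (stimulus-selective response potentiation);
* V1 only, single-1500 sessions: a decaying 10 Hz oscillation in the
  post-transient stationary window whose amplitude grows with familiarity.

Because every kernel parameter is known per subject and day, each analysis
stage downstream can be validated by parameter recovery.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocols import (
    DEFAULT_ORIENTATIONS,
    SessionProtocol,
    make_protocol,
)

__all__ = [
    "ComponentKernelParams",
    "NoiseParams",
    "OscillationParams",
    "PlasticityRule",
    "SubjectModel",
    "LfpRecording",
    "component_kernel",
    "default_subject_model",
    "evolve_model",
    "simulate_session",
    "simulate_cohort",
    "CohortDataset",
    "SCENARIOS",
    "WT_RULE",
    "AS_RULE",
]

SAMPLE_RATE_HZ = 1000.0
GAUSS_TRUNCATION_SIGMAS = 4.0


@dataclass
class ComponentKernelParams:
    """Shape of one evoked component: a negative lobe plus optional positivity.

    Latencies are ms relative to the onset of the driving stimulus; widths are
    Gaussian sigmas in ms; amplitudes are microvolts (both lobes stored as
    positive numbers, the negative lobe is subtracted).  ``lead_only``
    components are driven only by sequence-initial stimuli.
    """

    name: str
    neg_latency: float
    neg_amplitude: float
    neg_width: float
    pos_latency: float = 0.0
    pos_amplitude: float = 0.0
    pos_width: float = 1.0
    lead_only: bool = False

    def __post_init__(self) -> None:
        if self.neg_width <= 0 or self.pos_width <= 0:
            raise ValueError("lobe widths must be positive")
        if self.pos_amplitude > 0 and self.pos_latency <= self.neg_latency:
            raise ValueError("positive lobe must follow the negative lobe")


def _bump(grid: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Unit-peak Gaussian bump, truncated to zero beyond 4 sigma."""
    g = np.exp(-0.5 * ((grid - mu) / sigma) ** 2)
    g[np.abs(grid - mu) > GAUSS_TRUNCATION_SIGMAS * sigma] = 0.0
    return g


def component_kernel(params: ComponentKernelParams, grid: np.ndarray) -> np.ndarray:
    """Evaluate one component waveform (microvolts) on a time grid (ms)."""
    grid = np.asarray(grid, dtype=float)
    wave = -params.neg_amplitude * _bump(grid, params.neg_latency, params.neg_width)
    if params.pos_amplitude > 0:
        wave = wave + params.pos_amplitude * _bump(
            grid, params.pos_latency, params.pos_width
        )
    return wave


@dataclass
class NoiseParams:
    white_sd: float = 20.0    # microvolts per sample
    pink_scale: float = 10.0  # microvolts (SD of the 1/f component)


@dataclass
class OscillationParams:
    """Stationary-window oscillation added to V1 after sequence-initial onsets."""

    freq_hz: float = 10.0
    amplitude: float = 0.0          # microvolts at window start (0 disables)
    decay_ms: float = 1500.0
    window_ms: tuple[float, float] = (500.0, 1500.0)
    familiar_gain_by_day: dict[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 1.6, 3: 2.3, 4: 3.0}
    )


@dataclass
class PlasticityRule:
    """Day-indexed schedules for familiarity-driven parameter changes."""

    latency_shift_by_day: dict[int, float]
    v1_gain_by_day: dict[int, float]
    positivity_gain_by_day: dict[int, float]
    specific: bool = True  # restrict ACC effects to the familiar orientation

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.v1_gain_by_day.values()) or any(
            g < 0 for g in self.positivity_gain_by_day.values()
        ):
            raise ValueError("gains must be non-negative")


def _wt_rule() -> PlasticityRule:
    return PlasticityRule(
        latency_shift_by_day={1: 0.0, 2: -20.0, 3: -20.0, 4: -20.0},
        v1_gain_by_day={1: 1.0, 2: 1.2, 3: 1.35, 4: 1.5},
        positivity_gain_by_day={1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0},
    )


def _as_rule() -> PlasticityRule:
    return PlasticityRule(
        latency_shift_by_day={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
        v1_gain_by_day={1: 1.0, 2: 1.2, 3: 1.35, 4: 1.5},
        positivity_gain_by_day={1: 1.0, 2: 1.33, 3: 1.67, 4: 2.0},
    )


def _null_rule() -> PlasticityRule:
    """No programmed plasticity at all (null / calibration regime)."""
    flat0 = {d: 0.0 for d in range(1, 5)}
    flat1 = {d: 1.0 for d in range(1, 5)}
    return PlasticityRule(
        latency_shift_by_day=flat0,
        v1_gain_by_day=dict(flat1),
        positivity_gain_by_day=dict(flat1),
    )


WT_RULE = _wt_rule()
AS_RULE = _as_rule()
NULL_RULE = _null_rule()


@dataclass
class SubjectModel:
    """Generative parameters for one simulated subject (Day-1 baseline)."""

    subject_id: str
    genotype: str  # "WT" or "AS"
    region_params: dict[str, dict[str, list[ComponentKernelParams]]]
    plasticity: PlasticityRule
    noise: NoiseParams
    oscillation: OscillationParams
    orientation_map: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORIENTATIONS)
    )
    familiar_orientation: float = 45.0
    trained_orientations: frozenset[float] = frozenset({45.0})
    seed: int = 0
    day: int = 1  # set by evolve_model


def _acc_kernels(role: str, jit: dict[str, float]) -> list[ComponentKernelParams]:
    n1_amp = 30.0 if role in ("A", "N") else 25.0
    n1 = ComponentKernelParams(
        name="N1",
        neg_latency=jit["acc_n1_lat"],
        neg_amplitude=n1_amp * jit["amp"],
        neg_width=5.0,
    )
    n2 = ComponentKernelParams(
        name="N2",
        neg_latency=jit["acc_n2_lat"],
        neg_amplitude=25.0 * jit["amp"],
        neg_width=5.0,
        pos_latency=jit["acc_n2_lat"] + 75.0,
        pos_amplitude=15.0 * jit["amp"],
        pos_width=25.0,
        lead_only=True,
    )
    return [n1, n2]


def _v1_kernels(jit: dict[str, float]) -> list[ComponentKernelParams]:
    return [
        ComponentKernelParams(
            name="N1",
            neg_latency=jit["v1_n1_lat"],
            neg_amplitude=100.0 * jit["amp"],
            neg_width=8.0,
            pos_latency=jit["v1_n1_lat"] + 65.0,
            pos_amplitude=40.0 * jit["amp"],
            pos_width=20.0,
        )
    ]


def default_subject_model(
    genotype: str = "WT",
    subject_id: str = "s01",
    channels: tuple[str, ...] = ("ACC", "V1L", "V1R"),
    seed: int = 0,
    rng: np.random.Generator | None = None,
    trained_orientations: frozenset[float] = frozenset({45.0, 105.0, 15.0, 75.0}),
    oscillation_amplitude: float = 0.0,
) -> SubjectModel:
    """Build a subject model, with between-subject variability if ``rng`` given.

    Without ``rng`` the canonical Day-1 parameters are used exactly
    (ACC N1 at 60 ms, N2 at 185 ms with a positivity at 260 ms, V1 N1 at
    75 ms).  With ``rng``, latencies and an overall amplitude factor are
    jittered to emulate a cohort.
    """
    if genotype not in ("WT", "AS"):
        raise ValueError("genotype must be 'WT' or 'AS'")
    if rng is None:
        jit = {"acc_n1_lat": 60.0, "acc_n2_lat": 185.0, "v1_n1_lat": 75.0, "amp": 1.0}
    else:
        jit = {
            "acc_n1_lat": float(np.clip(rng.normal(60.0, 3.0), 50.0, 70.0)),
            "acc_n2_lat": float(np.clip(rng.normal(185.0, 6.0), 170.0, 200.0)),
            "v1_n1_lat": float(np.clip(rng.normal(75.0, 4.0), 65.0, 85.0)),
            "amp": float(np.exp(rng.normal(0.0, 0.12))),
        }
    roles = ("A", "B", "C", "D", "E", "N", "REVERSAL")
    region: dict[str, dict[str, list[ComponentKernelParams]]] = {}
    for ch in channels:
        if ch == "ACC":
            region[ch] = {r: _acc_kernels(r, jit) for r in roles}
        elif ch.startswith("V1"):
            region[ch] = {r: _v1_kernels(jit) for r in roles}
        else:
            raise ValueError(f"unknown channel {ch!r}")
    rule = _wt_rule() if genotype == "WT" else _as_rule()
    return SubjectModel(
        subject_id=subject_id,
        genotype=genotype,
        region_params=region,
        plasticity=rule,
        noise=NoiseParams(),
        oscillation=OscillationParams(amplitude=oscillation_amplitude),
        trained_orientations=trained_orientations,
        seed=seed,
    )


def evolve_model(
    model: SubjectModel, day: int, familiar_orientation: float | None = None
) -> SubjectModel:
    """Return the day-specific model derived from the Day-1 baseline.

    Always evolve from the baseline model (the schedules are absolute per
    day, not cumulative increments).  Non-familiar orientations are left
    untouched in ACC when the rule is orientation-specific; untrained
    orientations are left untouched in V1.
    """
    rule = model.plasticity
    if day not in rule.latency_shift_by_day:
        raise ValueError(f"day {day} outside the plasticity schedule")
    fam = model.familiar_orientation if familiar_orientation is None else familiar_orientation
    out = copy.deepcopy(model)
    out.day = day
    shift = rule.latency_shift_by_day[day]
    pos_gain = rule.positivity_gain_by_day[day]
    v1_gain = rule.v1_gain_by_day[day]
    for ch, per_role in out.region_params.items():
        for role, kernels in per_role.items():
            ori = out.orientation_map.get(role)
            if ch == "ACC":
                if rule.specific and ori != fam:
                    continue
                for k in kernels:
                    if k.name == "N2":
                        k.neg_latency += shift
                        if k.pos_amplitude > 0:
                            k.pos_latency += shift
                        k.pos_amplitude *= pos_gain
            elif ch.startswith("V1"):
                if ori not in out.trained_orientations:
                    continue
                for k in kernels:
                    k.neg_amplitude *= v1_gain
                    k.pos_amplitude *= v1_gain
    return out


@dataclass
class LfpRecording:
    """Continuous multichannel voltage (microvolts) with event alignment."""

    sample_rate: float
    t0_ms: float
    voltage: dict[str, np.ndarray]  # channel -> float32 series, equal length
    events: SessionProtocol | None = None

    @property
    def channels(self) -> list[str]:
        return list(self.voltage)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.voltage.values())))

    def validate(self) -> None:
        lengths = {len(v) for v in self.voltage.values()}
        if len(lengths) != 1:
            raise ValueError("channels must have equal length")


def _pink_noise(
    rng: np.random.Generator, n: int, scale: float, decimation: int = 4
) -> np.ndarray:
    """1/f-power noise of SD ``scale``, generated by spectral shaping.

    Synthesized at ``sample_rate / decimation`` and linearly upsampled: the
    1/f process is low-frequency dominated, so band-limiting it to 125 Hz
    (at the default 1 kHz rate) leaves the slow-drift statistics intact
    while the white component supplies the broadband floor.
    """
    if scale <= 0:
        return np.zeros(n, dtype=np.float32)
    from scipy.fft import irfft, next_fast_len, rfft

    m = next_fast_len(-(-n // decimation) + 1, real=True)
    spec = rfft(rng.standard_normal(m, dtype=np.float32))
    f = np.fft.rfftfreq(m, d=decimation / SAMPLE_RATE_HZ).astype(np.float32)
    spec[1:] /= np.sqrt(f[1:])
    spec[0] = 0.0
    coarse = irfft(spec, m)
    sd = coarse.std()
    if sd > 0:
        coarse *= scale / sd
    t = np.arange(n, dtype=np.float32) / decimation
    return np.interp(t, np.arange(m, dtype=np.float32), coarse).astype(np.float32)


def _event_template(
    kernels: list[ComponentKernelParams], lead: bool
) -> tuple[int, np.ndarray]:
    """Summed kernel waveform for one event; returns (offset_ms, waveform)."""
    active = [k for k in kernels if lead or not k.lead_only]
    if not active:
        return 0, np.zeros(1, dtype=np.float32)
    lo = min(k.neg_latency - GAUSS_TRUNCATION_SIGMAS * k.neg_width for k in active)
    hi = max(
        max(
            k.neg_latency + GAUSS_TRUNCATION_SIGMAS * k.neg_width,
            (k.pos_latency + GAUSS_TRUNCATION_SIGMAS * k.pos_width)
            if k.pos_amplitude > 0
            else 0.0,
        )
        for k in active
    )
    lo = int(np.floor(lo))
    hi = int(np.ceil(hi))
    grid = np.arange(lo, hi + 1, dtype=float)
    wave = np.zeros_like(grid)
    for k in active:
        wave += component_kernel(k, grid)
    return lo, wave.astype(np.float32)


def simulate_session(
    model: SubjectModel,
    protocol: SessionProtocol,
    seed: int | None = None,
    channels: list[str] | None = None,
) -> LfpRecording:
    """Synthesize one continuous session at 1 kHz.

    The voltage on each channel is the superposition of per-event kernels,
    white + pink noise, and (V1, sequence-initial events) the stationary-
    window oscillation.  Deterministic given ``seed`` (defaults to the
    model's own seed) and the channel list.
    """
    if channels is None:
        channels = list(model.region_params)
    rng = np.random.default_rng(model.seed if seed is None else seed)
    n = int(round(protocol.duration_ms * SAMPLE_RATE_HZ / 1000.0))
    osc = model.oscillation
    osc_day_gain = osc.familiar_gain_by_day.get(model.day, 1.0)

    voltage: dict[str, np.ndarray] = {}
    for ch in channels:
        per_role = model.region_params.get(ch)
        if per_role is None:
            raise ValueError(f"model has no parameters for channel {ch!r}")
        v = np.zeros(n, dtype=np.float32)
        templates: dict[tuple[str, bool], tuple[int, np.ndarray]] = {}
        for ev in protocol.events:
            if ev.role not in per_role:
                raise ValueError(f"unknown role/orientation {ev.role!r}")
            key = (ev.role, ev.seq_position == 1)
            if key not in templates:
                templates[key] = _event_template(per_role[ev.role], key[1])
            off, wave = templates[key]
            i0 = int(round(ev.onset)) + off
            a = max(i0, 0)
            b = min(i0 + len(wave), n)
            if b > a:
                v[a:b] += wave[a - i0 : b - i0]
        v += model.noise.white_sd * rng.standard_normal(n, dtype=np.float32)
        v += _pink_noise(rng, n, model.noise.pink_scale)
        if ch.startswith("V1") and osc.amplitude > 0:
            w0, w1 = osc.window_ms
            t_rel = np.arange(0.0, w1 - w0)
            envelope = np.exp(-t_rel / osc.decay_ms)
            for ev in protocol.events:
                if ev.seq_position != 1:
                    continue
                gain = osc_day_gain if ev.orientation == model.familiar_orientation else 1.0
                phase = rng.uniform(0.0, 2.0 * np.pi)
                i0 = int(round(ev.onset + w0))
                seg = (
                    osc.amplitude
                    * gain
                    * envelope
                    * np.sin(2.0 * np.pi * osc.freq_hz * t_rel / 1000.0 + phase)
                ).astype(np.float32)
                a, b = max(i0, 0), min(i0 + len(seg), n)
                if b > a:
                    v[a:b] += seg[a - i0 : b - i0]
        voltage[ch] = v

    rec = LfpRecording(
        sample_rate=SAMPLE_RATE_HZ, t0_ms=0.0, voltage=voltage, events=protocol
    )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------

#: figure-style experimental designs; ``novel`` describes the extra Day-4
#: session (kind, stimulus duration, orientation overrides, lead role)
SCENARIOS: dict[str, dict] = {
    "sequence-150": dict(
        kind="ABCD", duration=150.0, novel=("DCBA", 150.0, None, None),
        genotypes=("WT",), trained={45.0, 105.0, 15.0, 75.0}, oscillation=0.0,
    ),
    "sequence-300": dict(
        kind="ABCD", duration=300.0, novel=("DCBA", 300.0, None, None),
        genotypes=("WT",), trained={45.0, 105.0, 15.0, 75.0}, oscillation=0.0,
    ),
    "pseudorandom": dict(
        kind="AXXX", duration=300.0, novel=("NXXX", 300.0, None, "N"),
        genotypes=("WT",), trained={45.0, 105.0, 15.0, 75.0, 135.0}, oscillation=0.0,
    ),
    "single-300": dict(
        kind="SINGLE", duration=300.0, novel=("SINGLE", 300.0, {"N": 135.0}, "N"),
        genotypes=("WT",), trained={45.0}, oscillation=0.0,
    ),
    "single-300-null": dict(
        kind="SINGLE", duration=300.0, novel=None,
        genotypes=("WT",), trained={45.0}, oscillation=0.0, rule="null",
    ),
    "single-1500": dict(
        kind="SINGLE", duration=1500.0, novel=("SINGLE", 1500.0, {"N": 135.0}, "N"),
        genotypes=("WT",), trained={45.0}, oscillation=50.0,
    ),
    "genotype-contrast": dict(
        kind="ABCD", duration=300.0, novel=None,
        genotypes=("WT", "AS"), trained={45.0, 105.0, 15.0, 75.0}, oscillation=0.0,
    ),
}


@dataclass(frozen=True)
class RecordSpec:
    """One (subject, day, condition) session to be synthesized on demand."""

    subject_id: str
    genotype: str
    day: int
    condition: str  # "familiar" or "novel"
    kind: str
    duration: float
    orientation_overrides: dict | None
    lead_role: str | None
    protocol_seed: int
    lfp_seed: int


@dataclass
class CohortDataset:
    """Lazy cohort: subject models, session specs, and the ground-truth table.

    Recordings are synthesized on demand (:meth:`simulate` /
    :meth:`iter_sessions`) so that large cohorts never need to be held in
    memory at once; determinism is guaranteed by per-record seeds derived
    from the cohort seed.
    """

    scenario: str
    seed: int
    models: dict[str, SubjectModel]
    records: list[RecordSpec]
    channels: tuple[str, ...]

    def protocol_for(self, rec: RecordSpec) -> SessionProtocol:
        return make_protocol(
            rec.kind,
            day=rec.day,
            stimulus_duration=rec.duration,
            orientation_map=rec.orientation_overrides,
            seed=rec.protocol_seed,
            lead_role=rec.lead_role,
        )

    def simulate(
        self, rec: RecordSpec, channels: list[str] | None = None
    ) -> tuple[SessionProtocol, LfpRecording]:
        protocol = self.protocol_for(rec)
        model = evolve_model(self.models[rec.subject_id], rec.day)
        recording = simulate_session(
            model, protocol, seed=rec.lfp_seed, channels=channels
        )
        return protocol, recording

    def iter_sessions(self, channels: list[str] | None = None):
        for rec in self.records:
            protocol, recording = self.simulate(rec, channels=channels)
            yield rec, protocol, recording

    def truth(self) -> pd.DataFrame:
        """Ground truth: one row per (subject, day, channel, role, component)."""
        rows = []
        days = sorted({rec.day for rec in self.records})
        for sid, base in self.models.items():
            for day in days:
                model = evolve_model(base, day)
                for ch, per_role in model.region_params.items():
                    for role, kernels in per_role.items():
                        for k in kernels:
                            rows.append(
                                dict(
                                    subject=sid,
                                    genotype=model.genotype,
                                    day=day,
                                    channel=ch,
                                    role=role,
                                    component=k.name,
                                    neg_latency_ms=k.neg_latency,
                                    neg_amplitude_uv=k.neg_amplitude,
                                    neg_width_ms=k.neg_width,
                                    pos_latency_ms=k.pos_latency,
                                    pos_amplitude_uv=k.pos_amplitude,
                                    pos_width_ms=k.pos_width,
                                    lead_only=k.lead_only,
                                )
                            )
        return pd.DataFrame(rows)


def simulate_cohort(
    scenario: str,
    n_per_group: int = 8,
    days: int = 4,
    seed: int = 0,
    channels: tuple[str, ...] = ("ACC", "V1L", "V1R"),
    include_novel: bool | None = None,
) -> CohortDataset:
    """Assemble a reproducible cohort for one figure-style design.

    Each subject receives an independent :class:`SubjectModel` drawn from the
    population distributions; each (subject, day, condition) session gets its
    own derived seeds for the protocol and the voltage synthesis.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    cfg = SCENARIOS[scenario]
    novel = cfg["novel"] if include_novel in (None, True) else None
    if include_novel and cfg["novel"] is None:
        raise ValueError(f"scenario {scenario!r} has no novel condition")

    ss = np.random.SeedSequence(seed)
    models: dict[str, SubjectModel] = {}
    records: list[RecordSpec] = []
    subject_ids = [
        (g, f"{g.lower()}{i + 1:02d}")
        for g in cfg["genotypes"]
        for i in range(n_per_group)
    ]
    children = ss.spawn(len(subject_ids))
    for (genotype, sid), child in zip(subject_ids, children):
        model_rng = np.random.default_rng(child)
        models[sid] = default_subject_model(
            genotype=genotype,
            subject_id=sid,
            channels=channels,
            rng=model_rng,
            trained_orientations=frozenset(cfg["trained"]),
            oscillation_amplitude=cfg["oscillation"],
        )
        if cfg.get("rule") == "null":
            models[sid].plasticity = _null_rule()
        session_seeds = model_rng.integers(0, 2**31 - 1, size=2 * (days + 1))
        k = 0
        for day in range(1, days + 1):
            records.append(
                RecordSpec(
                    subject_id=sid,
                    genotype=genotype,
                    day=day,
                    condition="familiar",
                    kind=cfg["kind"],
                    duration=cfg["duration"],
                    orientation_overrides=None,
                    lead_role=None,
                    protocol_seed=int(session_seeds[k]),
                    lfp_seed=int(session_seeds[k + 1]),
                )
            )
            k += 2
        if novel is not None:
            nkind, ndur, nori, nlead = novel
            records.append(
                RecordSpec(
                    subject_id=sid,
                    genotype=genotype,
                    day=days,
                    condition="novel",
                    kind=nkind,
                    duration=ndur,
                    orientation_overrides=nori,
                    lead_role=nlead,
                    protocol_seed=int(session_seeds[k]),
                    lfp_seed=int(session_seeds[k + 1]),
                )
            )
    return CohortDataset(
        scenario=scenario, seed=seed, models=models, records=records, channels=channels
    )
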