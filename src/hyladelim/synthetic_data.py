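"""Synthetic data generators for every pipeline stage.

No machine-readable sequences, recordings, or occurrence data are shipped
with the package, so each downstream stage is exercised on synthetic inputs
whose statistical structure is known analytically:

* clade-structured alignments evolved under Jukes–Cantor on a star
  topology, so expected p-distances have a closed form;
* pulsed two-note-type frog calls (a long Type I trill, short Type II
  notes) built from a carrier sinusoid gated by raised-cosine pulses;
* normally distributed snout–vent-length (SVL) samples;
* point occurrence clouds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "CladeSimSpec",
    "NoteSpec",
    "CallSpec",
    "Waveform",
    "jc_expected_p",
    "jc_divergence_for_p",
    "simulate_alignment",
    "synthesize_call",
    "sample_svl",
    "sample_occurrences",
    "write_fasta",
    "write_clade_map",
    "write_wav",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Jukes–Cantor link


def jc_expected_p(d: float) -> float:
    """Expected uncorrected p-distance after ``d`` substitutions/site.

    Under Jukes–Cantor, p = 3/4 (1 - exp(-4d/3)); strictly increasing in
    ``d`` and saturating at 3/4.
    """
    if not math.isfinite(d) or d < 0:
        raise ValueError(f"divergence must be finite and >= 0, got {d!r}")
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def jc_divergence_for_p(p: float) -> float:
    """Inverse of :func:`jc_expected_p`: d = -3/4 ln(1 - 4p/3)."""
    if not 0 <= p < 0.75:
        raise ValueError(f"p must be in [0, 0.75), got {p!r}")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Alignments


@dataclass(frozen=True)
class CladeSimSpec:
    """One simulated mtDNA clade on the star topology.

    ``stem_divergence`` is the expected substitutions/site from the root to
    the clade ancestor; ``tip_divergence`` from the ancestor to each tip.
    The expected inter-clade p-distance between clades i and j is then
    ``jc_expected_p(stem_i + stem_j + tip_i + tip_j)`` and the expected
    intra-clade p-distance is ``jc_expected_p(2 * tip)``.
    """

    label: str
    n_tips: int
    stem_divergence: float
    tip_divergence: float

    def __post_init__(self) -> None:
        if self.n_tips < 1:
            raise ValueError(f"n_tips must be >= 1, got {self.n_tips}")
        for name in ("stem_divergence", "tip_divergence"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


def _evolve(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes–Cantor evolution of integer-coded sequence over divergence d.

    A site changes with probability 3/4 (1 - e^(-4d/3)) and, conditional on
    change, lands uniformly on one of the other three bases — exactly the JC
    transition kernel, so divergences compose additively along a path.
    """
    p_change = jc_expected_p(d)
    out = seq.copy()
    hit = rng.random(seq.size) < p_change
    n_hit = int(hit.sum())
    if n_hit:
        # uniform over the three other bases
        out[hit] = (seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return out


def simulate_alignment(
    specs: list[CladeSimSpec], seq_length: int, seed: int
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Simulate a clade-structured alignment under Jukes–Cantor.

    Returns ``(records, clade_map)`` where ``records`` is an ordered list of
    ``(id, sequence)`` pairs and ``clade_map`` maps each id to its clade
    label. The root sequence is i.i.d. uniform over {A,C,G,T}; each clade
    ancestor and each tip evolves independently under JC. Deterministic for
    a fixed seed.
    """
    if not specs:
        raise ValueError("at least one CladeSimSpec is required")
    if seq_length < 100:
        raise ValueError(f"seq_length must be >= 100, got {seq_length}")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("clade labels must be unique")

    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=seq_length)
    records: list[tuple[str, str]] = []
    clade_map: dict[str, str] = {}
    for spec in specs:
        ancestor = _evolve(root, spec.stem_divergence, rng)
        for i in range(spec.n_tips):
            tip = _evolve(ancestor, spec.tip_divergence, rng)
            sid = f"{spec.label}_{i + 1}"
            records.append((sid, _BASES[tip].tobytes().decode("ascii")))
            clade_map[sid] = spec.label
    return records, clade_map


# ---------------------------------------------------------------------------
# Calls


@dataclass(frozen=True)
class NoteSpec:
    """One pulsed note: ``n_pulses`` raised-cosine gated carrier pulses at
    ``pulse_period_s`` spacing, each pulse window ``pulse_duty`` of the
    period wide."""

    n_pulses: int
    pulse_period_s: float
    pulse_duty: float = 0.7

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError(f"n_pulses must be >= 1, got {self.n_pulses}")
        if self.pulse_period_s <= 0:
            raise ValueError("pulse_period_s must be > 0")
        if not 0 < self.pulse_duty <= 1:
            raise ValueError("pulse_duty must be in (0, 1]")

    @property
    def duration_s(self) -> float:
        return self.n_pulses * self.pulse_period_s


@dataclass(frozen=True)
class CallSpec:
    """A frog call: an ordered list of notes separated by silent gaps.

    Advertisement calls of the complex start with a long pulsed trill
    (Type I) optionally followed by shorter Type II notes; aggressive calls
    are series of Type II notes. ``amplitude_envelope`` gives the relative
    peak amplitude of each note in (0, 1].
    """

    notes: tuple[NoteSpec, ...]
    inter_note_gap_s: float = 0.046
    carrier_hz: float = 2748.69
    sample_rate_hz: int = 44100
    amplitude_envelope: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.notes:
            raise ValueError("a call must contain at least one note")
        if self.inter_note_gap_s <= 0:
            raise ValueError("inter_note_gap_s must be > 0")
        if self.carrier_hz <= 0:
            raise ValueError("carrier_hz must be > 0")
        if self.carrier_hz >= self.sample_rate_hz / 2:
            raise ValueError(
                f"carrier {self.carrier_hz} Hz is at or above Nyquist "
                f"({self.sample_rate_hz / 2} Hz)"
            )
        env = self.amplitude_envelope
        if not env:
            # first note loudest, secondary notes slightly softer
            env = (1.0,) + (0.8,) * (len(self.notes) - 1)
            object.__setattr__(self, "amplitude_envelope", env)
        if len(env) != len(self.notes):
            raise ValueError("amplitude_envelope must match the note count")
        if any(not 0 < a <= 1 for a in env):
            raise ValueError("amplitudes must be in (0, 1]")


@dataclass(frozen=True)
class Waveform:
    """Mono audio: samples in [-1, 1] at ``rate_hz``."""

    samples: np.ndarray
    rate_hz: int

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")
        if len(self.samples) < 1:
            raise ValueError("waveform must contain at least one sample")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate_hz


def _note_samples(
    note: NoteSpec, carrier_hz: float, rate: int, peak: float
) -> np.ndarray:
    """Render one note. Pulses are contiguous at pulse_period_s spacing;
    within the note, pulse amplitudes ramp up to a single maximum at ~60%
    of the note and decay slightly after, so the envelope maximum (hence
    rise time) is well defined."""
    n_note = round(note.duration_s * rate)
    t = np.arange(n_note) / rate
    out = np.zeros(n_note)
    n = note.n_pulses
    peak_idx = round(0.6 * (n - 1))
    for k in range(n):
        if n == 1:
            amp = 1.0
        elif k <= peak_idx:
            amp = 0.4 + 0.6 * (k / peak_idx if peak_idx else 1.0)
        else:
            amp = 1.0 - 0.15 * (k - peak_idx) / (n - 1 - peak_idx)
        start = k * note.pulse_period_s
        width = note.pulse_duty * note.pulse_period_s
        u = (t - start) / width
        window = np.where(
            (u >= 0) & (u <= 1), 0.5 * (1 - np.cos(2 * np.pi * u)), 0.0
        )
        out += amp * window
    return peak * out * np.sin(2 * np.pi * carrier_hz * t)


def synthesize_call(
    spec: CallSpec, seed: int = 0, noise_sd: float = 0.0
) -> Waveform:
    """Render a call to a mono waveform.

    Each pulse is the carrier sinusoid gated by a raised-cosine window of
    width ``pulse_duty * pulse_period_s``; notes are separated by silent
    gaps of ``inter_note_gap_s``. Optional additive white noise with
    standard deviation ``noise_sd`` (seeded). Peak |amplitude| <= 1 for
    noiseless calls.
    """
    rate = spec.sample_rate_hz
    pieces: list[np.ndarray] = []
    gap = np.zeros(round(spec.inter_note_gap_s * rate))
    for i, (note, amp) in enumerate(zip(spec.notes, spec.amplitude_envelope)):
        if i:
            pieces.append(gap)
        pieces.append(_note_samples(note, spec.carrier_hz, rate, amp))
    # short silent padding so envelope smoothing has room at the edges
    pad = np.zeros(round(0.02 * rate))
    samples = np.concatenate([pad, *pieces, pad])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, size=samples.size)
        samples = np.clip(samples, -1.0, 1.0)
    return Waveform(samples=samples, rate_hz=rate)


# ---------------------------------------------------------------------------
# SVL samples and occurrence clouds


def sample_svl(mean: float, sd: float, n: int, seed: int) -> np.ndarray:
    """i.i.d. normal snout–vent-length draws (mm); deterministic per seed."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    rng = np.random.default_rng(seed)
    return rng.normal(mean, sd, size=n)


def sample_occurrences(
    lon: float, lat: float, spread_deg: float, n: int, seed: int
) -> np.ndarray:
    """Gaussian cloud of ``n`` occurrence points (lon, lat) in WGS84
    decimal degrees around a centre; clipped to valid coordinate ranges."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    pts = rng.normal([lon, lat], spread_deg, size=(n, 2))
    pts[:, 0] = np.clip(pts[:, 0], -180.0, 180.0)
    pts[:, 1] = np.clip(pts[:, 1], -90.0, 90.0)
    return pts


# ---------------------------------------------------------------------------
# Writers (plain-text and WAV)


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write records as FASTA wrapped at 80 columns."""
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_clade_map(clade_map: dict[str, str], path: str | Path) -> None:
    """Write a two-column tab-delimited id → clade file."""
    with open(path, "w") as fh:
        fh.write("id\tclade\n")
        for sid, clade in clade_map.items():
            fh.write(f"{sid}\t{clade}\n")


def write_wav(w: Waveform, path: str | Path) -> None:
    """Write 16-bit PCM mono WAV."""
    scaled = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(str(path), w.rate_hz, (scaled * 32767).astype(np.int16))
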