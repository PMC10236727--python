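"""Huffman-coding compressibility as a single-trial ERP feature.

The thresholded wavelet coefficients of one trial/channel are rounded to the
nearest integer (half away from zero), the whole coefficient sequence in the
fixed band order [A4, D4, D3, D2, D1] is Huffman-encoded with a codebook
built from its own empirical symbol frequencies, and the feature is

    F = 100 / CR,      CR = x / x_c,

the compressed payload size x_c (bits) as a percentage of the original trial
size x = n_samples * 16 bits.  A trial dominated by a compact evoked
response thresholds to a sparse, highly compressible sequence (small F);
noisier or richer trials compress less (larger F).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .wavelet import (WaveletConfig, ThresholdedDecomposition,
                      threshold_with_energy_guard)

__all__ = [
    "BITS_PER_SAMPLE",
    "QuantizedCoefficients",
    "HuffmanCodebook",
    "Bitstream",
    "CompressionFeature",
    "FeatureMatrix",
    "CorruptBitstreamError",
    "EmptyClassError",
    "quantize",
    "build_codebook",
    "huffman_encode",
    "huffman_decode",
    "compression_feature",
    "trial_channel_feature",
    "build_feature_matrix",
    "build_feature_matrices",
]

#: 16-bit integer acquisition convention for the "original size" of a trial.
BITS_PER_SAMPLE = 16

#: Default coefficient quantization step in microvolts: the least significant
#: bit of a 16-bit EEG amplifier spanning +/-3.2768 mV.  Coefficients are
#: expressed in these ADC counts before integer rounding.
QUANTIZATION_STEP_UV = 0.1


class CorruptBitstreamError(ValueError):
    """Bitstream does not decode to a whole number of symbols."""


class EmptyClassError(ValueError):
    """All trials of an event class were flagged as artifacts."""


@dataclass
class QuantizedCoefficients:
    symbols: np.ndarray              # integer coefficients, band order fixed
    band_lengths: list[int]
    source_bits: int                 # original trial size x in bits


@dataclass
class HuffmanCodebook:
    symbols: list[int]
    probabilities: dict[int, float]
    codewords: dict[int, str]

    @property
    def code_lengths(self) -> dict[int, int]:
        return {s: len(w) for s, w in self.codewords.items()}

    @property
    def l_avg(self) -> float:
        """Expected code length sum_i P(a_i) l(a_i), bits/symbol."""
        return sum(self.probabilities[s] * len(self.codewords[s])
                   for s in self.symbols)

    @property
    def entropy(self) -> float:
        p = np.array([self.probabilities[s] for s in self.symbols])
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())


@dataclass
class Bitstream:
    bits: str

    @property
    def n_bits(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class CompressionFeature:
    cr: float      # compression ratio x / x_c
    f: float       # feature: 100 / CR, percent of original size


@dataclass
class FeatureMatrix:
    """m retained trials x n channels of the feature F for one event class."""

    values: np.ndarray
    event_class: str
    trial_ids: list[str]
    channel_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channel_ids)
        df.insert(0, "trial_id", self.trial_ids)
        df.insert(1, "label", self.event_class)
        return df


def _round_half_away(c: np.ndarray) -> np.ndarray:
    return np.trunc(c + np.copysign(0.5, c))


def quantize(decomp: ThresholdedDecomposition,
             bits_per_sample: int = BITS_PER_SAMPLE,
             step: float = 1.0) -> QuantizedCoefficients:
    """Round all retained coefficients to the nearest integer (half away from
    zero), concatenated coarse-to-fine: [A_J, D_J, ..., D_1].

    ``step`` is the quantization step: coefficients are divided by it before
    rounding, i.e. ``step=0.1`` rounds to ADC counts of a 0.1 uV/LSB
    amplifier while ``step=1.0`` rounds the raw coefficient values.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    flat = decomp.flatten() / step
    if not np.all(np.isfinite(flat)):
        raise ValueError("non-finite coefficient")
    symbols = _round_half_away(flat).astype(np.int64)
    return QuantizedCoefficients(symbols=symbols,
                                 band_lengths=decomp.band_lengths,
                                 source_bits=decomp.source_length
                                 * bits_per_sample)


def build_codebook(symbols: np.ndarray | list[int]) -> HuffmanCodebook:
    """Optimal prefix code for the empirical distribution of ``symbols``.

    Deterministic: node merges break ties on lower total weight, then lower
    minimum contained symbol; of the two merged nodes the smaller gets bit 0.
    A single-symbol alphabet gets a 1-bit codeword (a 0-bit code would make
    the compression ratio infinite).
    """
    symbols = np.asarray(symbols).ravel()
    if symbols.size == 0:
        raise ValueError("empty symbol sequence")
    values, counts = np.unique(symbols, return_counts=True)
    total = counts.sum()
    probabilities = {int(v): c / total for v, c in zip(values, counts)}
    if len(values) == 1:
        sym = int(values[0])
        return HuffmanCodebook(symbols=[sym], probabilities=probabilities,
                               codewords={sym: "0"})
    # heap entries: (weight, min contained symbol, node); node is either an
    # int leaf or a (left, right) pair
    heap: list = [(int(c), int(v), int(v)) for v, c in zip(values, counts)]
    heapq.heapify(heap)
    while len(heap) > 1:
        w0, m0, n0 = heapq.heappop(heap)
        w1, m1, n1 = heapq.heappop(heap)
        heapq.heappush(heap, (w0 + w1, min(m0, m1), (n0, n1)))
    codewords: dict[int, str] = {}

    def assign(node, prefix: str):
        if isinstance(node, tuple):
            assign(node[0], prefix + "0")
            assign(node[1], prefix + "1")
        else:
            codewords[node] = prefix

    assign(heap[0][2], "")
    return HuffmanCodebook(symbols=[int(v) for v in values],
                           probabilities=probabilities, codewords=codewords)


def huffman_encode(seq: np.ndarray | list[int],
                   codebook: HuffmanCodebook) -> Bitstream:
    """Concatenate codewords in sequence order."""
    seq = np.asarray(seq).ravel()
    if seq.size == 0:
        raise ValueError("empty sequence")
    try:
        bits = "".join(codebook.codewords[int(s)] for s in seq)
    except KeyError as exc:
        raise KeyError(f"symbol {exc.args[0]} not in codebook") from None
    return Bitstream(bits=bits)


def huffman_decode(stream: Bitstream,
                   codebook: HuffmanCodebook) -> np.ndarray:
    """Invert :func:`huffman_encode` exactly; trailing bits that do not
    complete a codeword raise :class:`CorruptBitstreamError`."""
    lookup = {w: s for s, w in codebook.codewords.items()}
    out: list[int] = []
    buf = ""
    for bit in stream.bits:
        buf += bit
        if buf in lookup:
            out.append(lookup[buf])
            buf = ""
    if buf:
        raise CorruptBitstreamError(
            f"{len(buf)} trailing bit(s) do not form a codeword")
    return np.asarray(out, dtype=np.int64)


def compression_feature(source_bits: int, stream: Bitstream
                        ) -> CompressionFeature:
    """``CR = x / x_c`` and ``F = 100 / CR`` from original and payload sizes."""
    if source_bits <= 0:
        raise ValueError("source_bits must be positive")
    if stream.n_bits == 0:
        raise ValueError("empty bitstream: compression ratio undefined")
    cr = source_bits / stream.n_bits
    return CompressionFeature(cr=cr, f=100.0 / cr)


def trial_channel_feature(x: np.ndarray,
                          config: WaveletConfig | None = None,
                          bits_per_sample: int = BITS_PER_SAMPLE,
                          step: float = QUANTIZATION_STEP_UV) -> float:
    """Full single-channel feature chain: energy-guarded thresholding ->
    integer quantization -> per-sequence Huffman codebook -> F."""
    thresholded = threshold_with_energy_guard(x, config)
    quantized = quantize(thresholded, bits_per_sample, step)
    codebook = build_codebook(quantized.symbols)
    stream = huffman_encode(quantized.symbols, codebook)
    return compression_feature(quantized.source_bits, stream).f


def build_feature_matrix(epochs: EpochSet, event_class: str,
                         config: WaveletConfig | None = None,
                         bits_per_sample: int = BITS_PER_SAMPLE,
                         step: float = QUANTIZATION_STEP_UV
                         ) -> FeatureMatrix:
    """Feature matrix (retained trials x channels) for one event class.

    Flagged (artifact) trials are excluded; each trial x channel vector is
    processed independently with its own codebook.
    """
    config = config or WaveletConfig()
    trials = [t for t in epochs.unflagged() if t.label == event_class]
    if not trials:
        raise EmptyClassError(
            f"no unflagged trials with label {event_class!r}")
    values = np.empty((len(trials), trials[0].n_channels))
    for i, trial in enumerate(trials):
        for j in range(trial.n_channels):
            values[i, j] = trial_channel_feature(trial.samples[:, j], config,
                                                 bits_per_sample, step)
    return FeatureMatrix(values=values, event_class=event_class,
                         trial_ids=[t.trial_id for t in trials],
                         channel_ids=list(epochs.channel_ids))


def build_feature_matrices(epochs: EpochSet,
                           config: WaveletConfig | None = None,
                           bits_per_sample: int = BITS_PER_SAMPLE,
                           step: float = QUANTIZATION_STEP_UV
                           ) -> dict[str, FeatureMatrix]:
    """One matrix per event class present among unflagged trials."""
    classes = sorted({t.label for t in epochs.unflagged()})
    return {c: build_feature_matrix(epochs, c, config, bits_per_sample, step)
            for c in classes}
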