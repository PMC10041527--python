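"""Signal-track preprocessing: peak calling, transforms, sampling, targets.

Tracks carry per-base signal on the -log10 P-value scale.  Peaks are called
by thresholding that signal and placing fixed-length intervals around each
exceedance, merging overlaps — mirroring standard consortium peak geometry.
Training examples are 1,000-bp sequence windows whose central 200 bp is the
target region, paired with a cells x features target matrix and the boolean
mask saying which entries were experimentally measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

PEAK_THRESHOLD = 4.4  # -log10 P-value cutoff matching consortium peak calls
PEAK_LENGTH = 150
WINDOW = 1000
TARGET_REGION = 200
UNMEASURED = np.nan

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SignalTrack:
    """Per-base non-negative signal for one (cell type, feature) pair."""

    chrom: str
    values: np.ndarray
    bin_size: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not np.isfinite(self.values).all():
            raise ValueError("signal values must be finite")


@dataclass(frozen=True)
class PeakInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("peak interval must have end > start")


@dataclass
class Sample:
    """One training example: sequence window + sparse target matrix."""

    chrom: str
    center: int
    sequence_window: str
    targets: np.ndarray  # cells x features
    measured_mask: np.ndarray  # cells x features bool

    @property
    def target_region(self) -> tuple:
        half = TARGET_REGION // 2
        return (self.center - half, self.center + half)


def call_peaks(
    track: SignalTrack,
    neglog_threshold: float = PEAK_THRESHOLD,
    peak_length: int = PEAK_LENGTH,
) -> list:
    """150-bp intervals centred on threshold exceedances, overlaps merged.

    Each position p with signal > threshold contributes the candidate
    [p - L/2, p + L/2); overlapping candidates are merged into maximal
    intervals, clipped to chromosome bounds, returned sorted.
    """
    if peak_length <= 0:
        raise ValueError("peak_length must be positive")
    half = peak_length // 2
    exceed = np.flatnonzero(track.values > neglog_threshold)
    if exceed.size == 0:
        return []
    if track.bin_size != 1:
        exceed = exceed * track.bin_size + track.bin_size // 2
    length = len(track.values) * track.bin_size
    starts = np.maximum(exceed - half, 0)
    ends = np.minimum(exceed + peak_length - half, length)
    peaks = []
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:  # overlapping or adjacent candidates merge
            cur_e = max(cur_e, int(e))
        else:
            peaks.append(PeakInterval(track.chrom, cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
    peaks.append(PeakInterval(track.chrom, cur_s, cur_e))
    return peaks


def transform_signal(
    values: np.ndarray,
    low_clip: float = -1.0,
    high_clip: float = 4.0,
    pseudocount: float = 1e-7,
) -> np.ndarray:
    """log10(value + pseudocount) clipped to [low_clip, high_clip]."""
    if low_clip > high_clip:
        raise ValueError("clip bounds must be ordered")
    return np.clip(np.log10(np.asarray(values, float) + pseudocount), low_clip, high_clip)


def sample_positions(
    peaks: list,
    extension: int = 30,
    min_spacing: int = 200,
    seed: int = 0,
    n_draws: int | None = None,
) -> list:
    """Draw sampling-point centres uniformly within extended peak intervals.

    Peaks are extended by `extension` bp on both sides (admitting peak-free
    flanks as negative examples); candidate centres are drawn uniformly over
    the union of extended intervals and accepted greedily in draw order iff
    at least `min_spacing` bp from every previously accepted centre.
    """
    if not peaks:
        return []
    rng = np.random.default_rng(seed)
    intervals = [(max(p.start - extension, 0), p.end + extension) for p in peaks]
    lengths = np.array([e - s for s, e in intervals], dtype=float)
    total = lengths.sum()
    if n_draws is None:
        n_draws = max(int(total // min_spacing) * 4, 8)
    probs = lengths / total
    picks = rng.choice(len(intervals), size=n_draws, p=probs)
    offsets = rng.random(n_draws)
    accepted: list[int] = []
    for i, u in zip(picks, offsets):
        s, e = intervals[i]
        pos = int(s + u * (e - s))
        if all(abs(pos - a) >= min_spacing for a in accepted):
            accepted.append(pos)
    return accepted


def encode_sequence(seq: str) -> np.ndarray:
    """One-hot encode a 1,000-bp sequence to a 4 x 1,000 matrix (rows A,C,G,T).

    Non-ACGT symbols yield all-zero columns.
    """
    if len(seq) != WINDOW:
        raise ValueError(f"sequence must be exactly {WINDOW} bp, got {len(seq)}")
    out = np.zeros((4, WINDOW))
    for j, base in enumerate(seq.upper()):
        i = _BASE_INDEX.get(base)
        if i is not None:
            out[i, j] = 1.0
    return out


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def build_targets(
    center: int,
    tracks_by_pair: dict,
    mask,
    mode: str,
    cage_features: set | None = None,
    genome: dict | None = None,
    chrom: str | None = None,
    neglog_threshold: float = PEAK_THRESHOLD,
    clip: tuple = (-1.0, 4.0),
    peaks_by_pair: dict | None = None,
) -> Sample:
    """Construct the Sample for one sampling point.

    Qualitative mode: label 1 iff a called peak of the (cell, feature) track
    overlaps the central 200-bp region by at least half the region (100 bp).
    Quantitative mode: max of the log-transformed signal over the region
    (sum for features in `cage_features`).  Unmeasured entries carry NaN and
    a False measured_mask.
    """
    if mode not in ("qualitative", "quantitative"):
        raise ValueError("mode must be 'qualitative' or 'quantitative'")
    cage_features = cage_features or set()
    half_w, half_r = WINDOW // 2, TARGET_REGION // 2
    if chrom is None:
        chrom = next(iter(tracks_by_pair.values())).chrom if tracks_by_pair else "chr1"
    if genome is not None:
        L = len(genome[chrom])
    else:
        L = max((len(t.values) for t in tracks_by_pair.values()), default=0)
    if center - half_w < 0 or center + half_w > L:
        raise ValueError(f"center {center} within {half_w} bp of a chromosome edge")
    r_start, r_end = center - half_r, center + half_r

    n_cells, n_features = mask.measured.shape
    targets = np.full((n_cells, n_features), UNMEASURED)
    measured = np.zeros((n_cells, n_features), dtype=bool)
    for (cell, feat), track in tracks_by_pair.items():
        r = mask.cell_index(cell)
        c = mask.feature_index(feat)
        if not mask.measured[r, c]:
            continue
        region = track.values[r_start:r_end]
        if mode == "qualitative":
            if peaks_by_pair is not None and (cell, feat) in peaks_by_pair:
                peaks = peaks_by_pair[(cell, feat)]
            else:
                peaks = call_peaks(track, neglog_threshold)
            hit = any(
                _overlap(p.start, p.end, r_start, r_end) >= TARGET_REGION // 2
                for p in peaks
            )
            targets[r, c] = float(hit)
        else:
            vals = transform_signal(region, *clip)
            targets[r, c] = vals.sum() if feat in cage_features else vals.max()
        measured[r, c] = True

    seq = genome[chrom][center - half_w : center + half_w] if genome is not None else "N" * WINDOW
    return Sample(chrom, center, seq, targets, measured)


# ---------------------------------------------------------------------------
# I/O


def read_bedgraph(path, chrom_lengths: dict) -> dict:
    """Read a 4-column bedGraph (0-based half-open) into per-chrom value arrays."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    out = {}
    for chrom, sub in df.groupby("chrom"):
        vals = np.zeros(chrom_lengths[chrom])
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            vals[s:e] = v
        out[chrom] = SignalTrack(chrom, vals)
    return out


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a SignalTrack as run-length-encoded 4-column bedGraph."""
    vals = track.values
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(vals)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            if vals[s] != 0.0:
                fh.write(f"{track.chrom}\t{s}\t{e}\t{vals[s]:.6g}\n")


def read_bigwig(path, chrom: str) -> SignalTrack:
    """Read one chromosome of a bigWig file (requires pyBigWig)."""
    import pyBigWig

    bw = pyBigWig.open(str(path))
    try:
        length = bw.chroms()[chrom]
        vals = np.nan_to_num(np.asarray(bw.values(chrom, 0, length), dtype=float))
    finally:
        bw.close()
    return SignalTrack(chrom, vals)


def write_peaks_bed(peaks: list, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


def read_fasta(path) -> dict:
    """Load a FASTA file into a dict of chromosome -> sequence string."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def save_samples(samples: list, path) -> None:
    """Persist Samples to an HDF5 container (coordinates + targets + masks)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("chrom", data=np.array([s.chrom for s in samples], dtype="S"))
        h5.create_dataset("center", data=np.array([s.center for s in samples]))
        h5.create_dataset(
            "sequence", data=np.array([s.sequence_window for s in samples], dtype="S")
        )
        h5.create_dataset("targets", data=np.stack([s.targets for s in samples]))
        h5.create_dataset("mask", data=np.stack([s.measured_mask for s in samples]))


def load_samples(path) -> list:
    with h5py.File(path, "r") as h5:
        chroms = [c.decode() for c in h5["chrom"][:]]
        centers = h5["center"][:]
        seqs = [s.decode() for s in h5["sequence"][:]]
        targets = h5["targets"][:]
        masks = h5["mask"][:]
    return [
        Sample(c, int(p), s, t, m)
        for c, p, s, t, m in zip(chroms, centers, seqs, targets, masks)
    ]
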