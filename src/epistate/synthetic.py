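"""Self-contained synthetic world generator for end-to-end testing.

The generator emulates the statistical structure the model assumes:

* a toy genome (random ACGT) with short motifs planted at known positions;
* cell types organized into latent groups; each group has an activity factor
  per motif, so cells in the same group share regulatory behaviour;
* per-(cell, feature) signal tracks on the -log10 P-value scale, built as
  sums of feature-weight x group-factor products under a triangular proximity
  kernel around each planted motif occurrence, plus half-normal noise;
* a sparse but connected cell x feature measurement mask.

Group labels double as tissue labels, providing ground truth for
embedding-clustering analyses.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .track_graph import MeasurementMatrix, is_connected
from .tracks import SignalTrack, write_bedgraph

KERNEL_HALF_WIDTH = 75  # matches the 150-bp peak geometry downstream


@dataclass
class SyntheticConfig:
    genome_length: int = 60_000
    n_chromosomes: int = 1
    n_cell_types: int = 12
    n_cell_groups: int = 3
    n_features: int = 4
    motifs: list = field(default_factory=lambda: ["TGACTCAG", "GGCCAATC", "CACGTGAC"])
    feature_motif_weights: np.ndarray | None = None
    group_factor_matrix: np.ndarray | None = None
    occurrences_per_motif: int = 10
    noise_sd: float = 0.25
    mask_density: float = 0.4
    shared_background: bool = False
    seed: int = 0

    def __post_init__(self):
        if not self.motifs:
            raise ValueError("at least one motif is required")
        for m in self.motifs:
            if not (6 <= len(m) <= 10) or set(m) - set("ACGT"):
                raise ValueError(f"motif {m!r} must be 6-10 bp of ACGT")
        if self.n_cell_groups > self.n_cell_types:
            raise ValueError("n_cell_groups must not exceed n_cell_types")
        if not (0 < self.mask_density <= 1):
            raise ValueError("mask_density must be in (0, 1]")
        n_m = len(self.motifs)
        if self.feature_motif_weights is None:
            # every feature responds to every motif, with amplitudes 5..8 so a
            # fully active site clears the 4.4 peak threshold; which sites are
            # active in a given cell is decided by its group's factors, so the
            # across-cell mean profile is uninformative about cell identity
            self.feature_motif_weights = 5.0 + np.add.outer(
                np.arange(self.n_features), np.arange(n_m)
            ) % 4
        self.feature_motif_weights = np.asarray(self.feature_motif_weights, float)
        if self.group_factor_matrix is None:
            # each group activates one motif strongly, the rest weakly
            f = np.full((self.n_cell_groups, n_m), 0.1)
            for g in range(self.n_cell_groups):
                f[g, g % n_m] = 1.0
            self.group_factor_matrix = f
        self.group_factor_matrix = np.asarray(self.group_factor_matrix, float)
        if not np.isfinite(self.feature_motif_weights).all():
            raise ValueError("feature_motif_weights must be finite")
        if not np.isfinite(self.group_factor_matrix).all():
            raise ValueError("group_factor_matrix must be finite")
        if self.group_factor_matrix.min() < 0 or self.group_factor_matrix.max() > 1:
            raise ValueError("group_factor_matrix entries must lie in [0, 1]")
        if self.feature_motif_weights.shape != (self.n_features, n_m):
            raise ValueError("feature_motif_weights shape mismatch")
        if self.group_factor_matrix.shape != (self.n_cell_groups, n_m):
            raise ValueError("group_factor_matrix shape mismatch")


@dataclass
class SyntheticWorld:
    genome: dict  # chrom -> sequence string
    cell_group_of: dict  # cell id -> group index
    tracks: dict  # (cell, feature) -> SignalTrack
    mask: MeasurementMatrix
    truth: list  # (chrom, pos, motif index) planted occurrences
    config: SyntheticConfig

    @property
    def cells(self) -> list:
        return self.mask.cells

    @property
    def features(self) -> list:
        return self.mask.features


def generate_measurement_mask(
    n_cells: int, n_features: int, mask_density: float, seed: int
) -> MeasurementMatrix:
    """Random connected mask with >=1 measurement per cell and per feature.

    Built as a random bipartite spanning tree (guaranteeing connectivity and
    full row/column coverage) plus uniform extra edges up to the requested
    density.
    """
    n_edges = int(round(mask_density * n_cells * n_features))
    min_edges = n_cells + n_features - 1
    if n_edges < min_edges:
        raise ValueError(
            f"mask_density {mask_density} gives {n_edges} edges but connecting "
            f"{n_cells} cells and {n_features} features needs >= {min_edges}"
        )
    rng = np.random.default_rng(seed)
    measured = np.zeros((n_cells, n_features), dtype=bool)
    cell_order = rng.permutation(n_cells)
    feat_order = rng.permutation(n_features)
    # spanning tree: attach each new node to a random already-connected node
    # on the other side of the bipartition
    in_cells = [cell_order[0]]
    in_feats = [feat_order[0]]
    measured[in_cells[0], in_feats[0]] = True
    next_cell, next_feat = 1, 1
    while next_cell < n_cells or next_feat < n_features:
        add_cell = next_cell < n_cells and (
            next_feat >= n_features or rng.random() < 0.5
        )
        if add_cell:
            c = cell_order[next_cell]
            measured[c, in_feats[rng.integers(len(in_feats))]] = True
            in_cells.append(c)
            next_cell += 1
        else:
            f = feat_order[next_feat]
            measured[in_cells[rng.integers(len(in_cells))], f] = True
            in_feats.append(f)
            next_feat += 1
    # fill remaining edges uniformly at random
    free = np.flatnonzero(~measured.ravel())
    extra = n_edges - int(measured.sum())
    if extra > 0:
        chosen = rng.choice(free, size=min(extra, free.size), replace=False)
        measured.ravel()[chosen] = True
    cells = [f"cell{i:02d}" for i in range(n_cells)]
    feats = [f"feat{j}" for j in range(n_features)]
    m = MeasurementMatrix(cells, feats, measured)
    assert is_connected(m)
    return m


def _triangular_profile(length: int, centers: np.ndarray, half_width: int) -> np.ndarray:
    """max over occurrences of max(0, 1 - d/half_width) at each position."""
    prof = np.zeros(length)
    pos = np.arange(length)
    for c in centers:
        lo, hi = max(0, c - half_width), min(length, c + half_width + 1)
        seg = 1.0 - np.abs(pos[lo:hi] - c) / half_width
        np.maximum(prof[lo:hi], seg, out=prof[lo:hi])
    return prof


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Generate genome, planted motifs, group-structured tracks and mask.

    Signal at position p for (cell n, feature k):
        sum_m  W[k, m] * F[group(n), m] * tri(p, nearest occurrence of m)
        + |Normal(0, noise_sd)|
    where tri is a triangular kernel of half-width 75 bp.  Deterministic
    given config.seed.
    """
    rng = np.random.default_rng(config.seed)
    chrom_len = config.genome_length // config.n_chromosomes
    n_motifs = len(config.motifs)
    # with a shared background the genome tiles one fixed template, so any
    # two windows differ only by motif content and offset; occurrences get a
    # +/-150 bp jitter (slots widened to keep every pair >= 1,000 bp apart)
    spacing = 1300 if config.shared_background else 1000
    slots_per_chrom = chrom_len // spacing - 1
    total_slots = slots_per_chrom * config.n_chromosomes
    need = config.occurrences_per_motif * n_motifs
    if total_slots < need:
        raise ValueError(
            f"genome too short: {need} motif occurrences need {need} slots "
            f">= {spacing} bp apart, only {total_slots} available"
        )

    genome = {}
    truth = []
    bases = np.array(list("ACGT"))
    slot_ids = rng.permutation(total_slots)[:need]
    motif_of_slot = rng.permutation(np.repeat(np.arange(n_motifs), config.occurrences_per_motif))
    placements: dict = {}
    for slot, mi in zip(slot_ids, motif_of_slot):
        ci, si = divmod(slot, slots_per_chrom)
        # one occurrence per slot, at the slot centre (jittered when the
        # background is shared), so any two occurrences are >= 1,000 bp apart
        pos = si * spacing + spacing // 2
        if config.shared_background:
            pos += int(rng.integers(-150, 151))
        placements.setdefault(ci, []).append((pos, int(mi)))
    if config.shared_background:
        template = rng.choice(bases, size=spacing)
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        if config.shared_background:
            reps = chrom_len // spacing + 1
            seq = np.tile(template, reps)[:chrom_len].copy()
        else:
            seq = rng.choice(bases, size=chrom_len)
        for pos, mi in sorted(placements.get(ci, [])):
            motif = config.motifs[mi]
            seq[pos : pos + len(motif)] = list(motif)
            truth.append((chrom, pos, mi))
        genome[chrom] = "".join(seq)

    mask = generate_measurement_mask(
        config.n_cell_types, config.n_features, config.mask_density, config.seed + 1
    )
    group_of = {
        cell: i % config.n_cell_groups for i, cell in enumerate(mask.cells)
    }

    # per-(chrom, motif) proximity profiles, shared across tracks
    profiles = {}
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        for mi in range(n_motifs):
            centers = np.array(
                [p for (c, p, m) in truth if c == chrom and m == mi], dtype=int
            )
            profiles[(chrom, mi)] = _triangular_profile(
                chrom_len, centers, KERNEL_HALF_WIDTH
            )

    tracks = {}
    W, F = config.feature_motif_weights, config.group_factor_matrix
    for r, c in zip(*np.nonzero(mask.measured)):
        cell, feat = mask.cells[r], mask.features[c]
        g = group_of[cell]
        for ci in range(config.n_chromosomes):
            chrom = f"chr{ci + 1}"
            vals = np.zeros(chrom_len)
            for mi in range(n_motifs):
                vals += W[c, mi] * F[g, mi] * profiles[(chrom, mi)]
            if config.noise_sd > 0:
                vals += np.abs(rng.normal(0.0, config.noise_sd, size=chrom_len))
            key = (cell, feat) if config.n_chromosomes == 1 else (cell, feat, chrom)
            tracks[key] = SignalTrack(chrom, vals)

    return SyntheticWorld(genome, group_of, tracks, mask, truth, config)


def emit_fixture_files(world: SyntheticWorld, out_dir) -> dict:
    """Write the world to disk: FASTA genome, bedGraph tracks, TSV metadata.

    Returns a manifest mapping logical names to written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"tracks": {}}

    fasta = os.path.join(out_dir, "genome.fa")
    with open(fasta, "w") as fh:
        for chrom, seq in world.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    manifest["genome"] = fasta

    for key, track in world.tracks.items():
        cell, feat = key[0], key[1]
        path = os.path.join(out_dir, f"{cell}__{feat}.bedGraph")
        write_bedgraph(track, path)
        manifest["tracks"][f"{cell}__{feat}"] = path

    mask_path = os.path.join(out_dir, "mask.tsv")
    world.mask.to_tsv(mask_path)
    manifest["mask"] = mask_path

    meta_path = os.path.join(out_dir, "cells.tsv")
    pd.DataFrame(
        {
            "cell_id": world.cells,
            "tissue_label": [f"group{world.cell_group_of[c]}" for c in world.cells],
        }
    ).to_csv(meta_path, sep="\t", index=False)
    manifest["cell_metadata"] = meta_path

    cfg_path = os.path.join(out_dir, "config.json")
    cfg = asdict(world.config)
    for k, v in cfg.items():
        if isinstance(v, np.ndarray):
            cfg[k] = v.tolist()
    with open(cfg_path, "w") as fh:
        json.dump(cfg, fh, indent=2)
    manifest["config"] = cfg_path
    return manifest
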