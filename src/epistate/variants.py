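"""Variant effect scoring by reference-vs-alternative prediction differences.

For a single-nucleotide variant, the model predicts all (cell type, feature)
outputs for the 1,000-bp window carrying the reference base and again with
the alternative base substituted; the per-track difference
(reference - alternative) is the cell-type-specific effect of the variant on
that feature, summarized by its maximum absolute value over all tracks.
Effects are produced for every combination, including tracks never measured
experimentally.

The eQTL concordance analysis averages effects over the cell types of each
tissue, orients them by the reported direction of the expression effect, and
compares significant vs nonsignificant variants per (tissue, feature) with a
t-test under a Bonferroni correction across tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import WINDOW, encode_sequence

_BASES = set("ACGT")


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide variants are supported")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"malformed alleles {self.ref!r}/{self.alt!r}")


@dataclass
class EffectRecord:
    variant: Variant
    effects: np.ndarray  # cells x features, ref prediction - alt prediction

    @property
    def max_abs_effect(self) -> float:
        return float(np.abs(self.effects).max())

    @property
    def argmax(self) -> tuple:
        idx = np.unravel_index(np.argmax(np.abs(self.effects)), self.effects.shape)
        return (int(idx[0]), int(idx[1]))


@dataclass(frozen=True)
class EqtlRecord:
    variant: Variant
    tissue: str
    effect_sign: int  # +1 or -1
    significant: bool

    def __post_init__(self):
        if self.effect_sign not in (1, -1):
            raise ValueError("effect_sign must be +1 or -1")


def filter_variants(variants: list, tss_table: dict, window: int = 50_000) -> list:
    """Keep SNVs within +/- `window` bp of any transcription start; deduplicate.

    `tss_table` maps gene -> (chrom, position).  Indels never reach this
    function (the Variant constructor rejects them); records failing the
    distance filter or duplicating an earlier (chrom, pos, ref, alt) key are
    dropped.
    """
    if not tss_table:
        raise ValueError("tss_table must be non-empty")
    by_chrom: dict = {}
    for gene, (chrom, pos) in tss_table.items():
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom in by_chrom:
        by_chrom[chrom] = np.sort(np.asarray(by_chrom[chrom]))
    seen = set()
    kept = []
    for v in variants:
        key = (v.chrom, v.pos, v.ref, v.alt)
        if key in seen:
            continue
        tss = by_chrom.get(v.chrom)
        if tss is None or np.abs(tss - v.pos).min() > window:
            continue
        seen.add(key)
        kept.append(v)
    return kept


def predict_effects(
    model,
    genome: dict,
    variant: Variant,
    cells=None,
    strict: bool = True,
    component: str = "combined",
) -> EffectRecord:
    """Effect matrix for one variant: prediction(ref) - prediction(alt).

    The 1,000-bp window is centred on the variant (variant at offset 500).
    `component` selects the output of a split-head model: 'combined' (M + D,
    cell-specific) or 'M' (sequence-only, cell-agnostic scoring).
    """
    chrom_seq = genome[variant.chrom]
    p0 = variant.pos - 1  # to 0-based
    half = WINDOW // 2
    if p0 - half < 0 or p0 + half > len(chrom_seq):
        raise ValueError(f"variant at {variant.pos} is within 500 bp of a chromosome end")
    window = chrom_seq[p0 - half : p0 + half]
    genome_base = window[half].upper()
    if genome_base != variant.ref:
        msg = f"reference allele {variant.ref} does not match genome base {genome_base}"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg)
    # both alleles are substituted symmetrically, so swapping ref and alt
    # negates the effect matrix exactly
    ref_window = window[:half] + variant.ref + window[half + 1 :]
    alt_window = window[:half] + variant.alt + window[half + 1 :]

    X = np.stack([encode_sequence(ref_window), encode_sequence(alt_window)])
    if component == "M":
        M, _, _ = model.predict_split(X, cells)
        n_cells = model.n_cells_ if cells is None else len(cells)
        ref_pred = np.broadcast_to(M[0], (n_cells, M.shape[1]))
        alt_pred = np.broadcast_to(M[1], (n_cells, M.shape[1]))
    else:
        preds = model.predict(X, cells)
        ref_pred, alt_pred = preds[0], preds[1]
    return EffectRecord(variant, np.asarray(ref_pred) - np.asarray(alt_pred))


def summarize_cohort(
    effects_affected: list, effects_sibling: list, mask=None
) -> pd.DataFrame:
    """Per-track mean |effect| difference between two variant cohorts.

    One row per (cell index, feature index) track: mean absolute effect over
    the affected cohort minus the same over the sibling cohort, flagged
    'measured' from the measurement matrix when given.
    """
    if not effects_affected or not effects_sibling:
        raise ValueError("both cohorts must be non-empty")
    aff = np.mean([np.abs(e.effects) for e in effects_affected], axis=0)
    sib = np.mean([np.abs(e.effects) for e in effects_sibling], axis=0)
    diff = aff - sib
    n_cells, n_features = diff.shape
    rows = []
    for n in range(n_cells):
        for k in range(n_features):
            rows.append(
                {
                    "cell": n,
                    "feature": k,
                    "mean_abs_affected": aff[n, k],
                    "mean_abs_sibling": sib[n, k],
                    "difference": diff[n, k],
                    "measured": bool(mask.measured[n, k]) if mask is not None else None,
                }
            )
    return pd.DataFrame(rows)


def gtex_score(
    effects: list,
    tissue_cells: dict,
    eqtl: list,
    features: list | None = None,
    orientation: str = "ref-alt",
) -> pd.DataFrame:
    """Signed per-(variant, tissue, feature) functional scores.

    score(v, tissue, k) = sign(v, tissue) x mean over the tissue's cells of
    the variant's effect on feature k.  Variants reported with opposite
    effect signs across tissues are excluded.  `features` restricts scoring
    to a caller-selected feature subset (e.g. features with adequate AP and
    sample counts).  `orientation` selects the allele-difference convention:
    'ref-alt' uses the EffectRecord convention directly, 'alt-ref' negates
    it (scoring the alternative allele's gain over the reference).
    """
    if orientation not in ("ref-alt", "alt-ref"):
        raise ValueError("orientation must be 'ref-alt' or 'alt-ref'")
    flip = -1.0 if orientation == "alt-ref" else 1.0
    eff_by_variant = {e.variant: e for e in effects}
    signs_by_variant: dict = {}
    for rec in eqtl:
        signs_by_variant.setdefault(rec.variant, set()).add(rec.effect_sign)
    pleiotropic = {v for v, s in signs_by_variant.items() if len(s) > 1}

    rows = []
    for rec in eqtl:
        if rec.variant in pleiotropic or rec.variant not in eff_by_variant:
            continue
        cells = tissue_cells.get(rec.tissue)
        if not cells:
            raise ValueError(f"tissue {rec.tissue} has no mapped cells")
        e = eff_by_variant[rec.variant].effects
        tissue_mean = e[np.asarray(cells, int)].mean(axis=0)
        n_features = e.shape[1]
        feat_iter = features if features is not None else range(n_features)
        for k in feat_iter:
            rows.append(
                {
                    "variant": rec.variant.id or f"{rec.variant.chrom}:{rec.variant.pos}",
                    "tissue": rec.tissue,
                    "feature": k,
                    "score": flip * rec.effect_sign * tissue_mean[k],
                    "significant": rec.significant,
                }
            )
    return pd.DataFrame(rows)


def gtex_test(
    scores: pd.DataFrame,
    n_tissues: int = 22,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(tissue, feature) t-test, significant vs nonsignificant variants.

    The significance cutoff is Bonferroni-adjusted over tissues only
    (family_alpha / n_tissues), not over features.
    """
    threshold = family_alpha / n_tissues
    rows = []
    for (tissue, feature), sub in scores.groupby(["tissue", "feature"]):
        sig = sub.loc[sub["significant"], "score"].to_numpy()
        non = sub.loc[~sub["significant"], "score"].to_numpy()
        if len(sig) < 2 or len(non) < 2:
            continue
        if sig.std() == 0 and non.std() == 0:
            raise ValueError(f"degenerate variance in both groups for {tissue}/{feature}")
        t, p = stats.ttest_ind(sig, non, equal_var=False)
        rows.append(
            {
                "tissue": tissue,
                "feature": feature,
                "t": float(t),
                "p": float(p),
                "significant": bool(p < threshold),
                "threshold": threshold,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def read_variants_vcf(path) -> list:
    """Read SNVs from an (uncompressed or bgzipped) VCF file."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1 and rec.ref != alt:
                    out.append(Variant(rec.chrom, rec.pos, rec.ref, alt, rec.id))
    return out


def read_variants_tsv(path) -> list:
    """Read variants from a TSV with columns chrom, pos, ref, alt [, id]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        vid = getattr(row, "id", None)
        out.append(Variant(str(row.chrom), int(row.pos), str(row.ref), str(row.alt), vid))
    return out


def write_effects_tsv(records: list, long_path, summary_path) -> None:
    """Long-format per-track effects plus a per-variant summary table."""
    long_rows, summary_rows = [], []
    for rec in records:
        v = rec.variant
        vid = v.id or f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}"
        n_cells, n_features = rec.effects.shape
        for n in range(n_cells):
            for k in range(n_features):
                long_rows.append(
                    {"variant": vid, "cell": n, "feature": k, "effect": rec.effects[n, k]}
                )
        amax = rec.argmax
        summary_rows.append(
            {
                "variant": vid,
                "max_abs_effect": rec.max_abs_effect,
                "argmax_cell": amax[0],
                "argmax_feature": amax[1],
            }
        )
    pd.DataFrame(long_rows).to_csv(long_path, sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)
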