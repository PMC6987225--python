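"""Observed vs expected counts of consensus-derived motifs over gene regions.

A 6-bp window can match the full consensus hexamer, one of the two
quintets (five consecutive consensus bases, positions 1-5 or 2-6 of the
frame) or one of the three quartets (four consecutive consensus bases,
positions 1-4, 2-5 or 3-6).  For a genome of A/T content ``at``, each
consensus base (always A or T) is matched with probability
``p = at / 2``, so over the ``L - 5`` windows of an L-bp sequence the
expected counts are ``p^6 (L-5)`` for the consensus, ``(1-p) p^5 (L-5)``
per quintet variant and ``(1-p)^2 p^4 (L-5)`` per quartet variant; the
``(1-p)`` factors avoid over-counting windows that also match a higher
class.  Observed counting mirrors this: a window counts for a variant
only if the remaining in-frame positions mismatch their consensus base.

Counts are taken on the supplied strand only.  Because the consensus is
palindromic and the two quintet variants are mutual reverse complements,
single-strand counting of all variants is equivalent to one-variant
counting over both strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tfantenna.sequence_io import GeneModel, SequenceRecord, SequenceError

logger = logging.getLogger(__name__)

MOTIF_CLASSES = ("consensus", "quintet", "quartet")


@dataclass(frozen=True)
class MotifClass:
    """Variants of one motif class within the 6-bp frame.

    Each variant is the tuple of 0-based frame positions that must match
    the consensus base; the remaining in-frame positions must mismatch.
    """

    name: str
    variants: tuple[tuple[int, ...], ...]
    consensus: str = "TAATTA"

    @classmethod
    def make(cls, name: str, consensus: str = "TAATTA") -> "MotifClass":
        if name == "consensus":
            variants = (tuple(range(6)),)
        elif name == "quintet":
            variants = (tuple(range(0, 5)), tuple(range(1, 6)))
        elif name == "quartet":
            variants = (tuple(range(0, 4)), tuple(range(1, 5)), tuple(range(2, 6)))
        else:
            raise ValueError(f"unknown motif class {name!r}")
        return cls(name=name, variants=variants, consensus=consensus)

    def variant_label(self, variant: tuple[int, ...]) -> str:
        return "".join(self.consensus[k] for k in variant) + f"@{variant[0] + 1}"


def expected_count(
    motif: MotifClass, length: int, at_content: float
) -> dict[tuple[int, ...], float]:
    """Expected count per variant for an L-bp sequence of given A/T content.

    ``p = at_content / 2`` per matched position; ``(1 - p)`` per required
    mismatch; ``L - 5`` windows.  Lengths below 6 yield 0 with a warning.
    """
    if not 0.0 <= at_content <= 1.0:
        raise ValueError("at_content must be in [0, 1]")
    if length < 6:
        logger.warning("sequence of %d bp has no 6-bp windows", length)
        return {v: 0.0 for v in motif.variants}
    p = at_content / 2.0
    n_windows = length - 5
    out = {}
    for variant in motif.variants:
        n_match = len(variant)
        n_miss = 6 - n_match
        out[variant] = (1.0 - p) ** n_miss * p**n_match * n_windows
    return out


def _window_matches(window: str, variant: tuple[int, ...], consensus: str) -> bool:
    """Exclusion-rule match: specified positions equal the consensus base,
    all other in-frame positions differ from it."""
    spec = set(variant)
    for k in range(6):
        if k in spec:
            if window[k] != consensus[k]:
                return False
        else:
            if window[k] == consensus[k]:
                return False
    return True


def observed_count(
    record: SequenceRecord | str,
    motif: MotifClass,
    mask: np.ndarray | None = None,
) -> dict[tuple[int, ...], int]:
    """Count motif-variant occurrences over all 6-bp windows of one strand.

    ``mask``, when given, is a boolean array over sequence positions; a
    window is counted only when its first base lies in the mask (the
    first-base attribution rule for windows straddling region boundaries).
    """
    bases = record.bases if isinstance(record, SequenceRecord) else record
    n = len(bases)
    counts = {v: 0 for v in motif.variants}
    if n < 6:
        return counts
    for i in range(n - 5):
        if mask is not None and not mask[i]:
            continue
        window = bases[i : i + 6]
        for variant in motif.variants:
            if _window_matches(window, variant, motif.consensus):
                counts[variant] += 1
    return counts


def region_partition(
    gene: GeneModel, record: SequenceRecord
) -> tuple[list[tuple[int, str]], list[tuple[int, str]]]:
    """Split a record into (regulatory, CDS) subsequences with offsets.

    Intervals are interpreted in record coordinates and must lie within
    the record; returns lists of ``(start, subsequence)``.
    """
    if gene.span[1] > record.n:
        raise SequenceError(
            f"gene span {gene.span} outside record {record.id!r} ({record.n} bp)"
        )
    rr = [(s, record.bases[s:e]) for s, e in gene.regulatory]
    cds = [(s, record.bases[s:e]) for s, e in gene.cds]
    return rr, cds


def _cds_mask(gene: GeneModel, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in gene.cds:
        mask[s:e] = True
    return mask


def enrichment_table(
    record: SequenceRecord,
    gene: GeneModel,
    at_content: float = 0.57,
    consensus: str = "TAATTA",
) -> pd.DataFrame:
    """Observed, expected and ratio per motif class and region.

    Observed counts over the whole extended span attribute each window to
    the region containing its first base; the regulatory-region count is
    the whole-span count minus the CDS count, so the three region rows are
    additive by construction.  Expected counts treat each region fragment
    independently with ``L - 5`` windows.  Rows for empty regions, or with
    zero expectation, report NA ratios.
    """
    if gene.span[1] > record.n:
        raise SequenceError(
            f"gene span {gene.span} outside record {record.id!r} ({record.n} bp)"
        )
    span_s, span_e = gene.span
    span_seq = record.bases[span_s:span_e]
    cds_mask_full = _cds_mask(gene, record.n)[span_s:span_e]

    rows = []
    for cls_name in MOTIF_CLASSES:
        motif = MotifClass.make(cls_name, consensus)
        obs_whole = observed_count(span_seq, motif)
        obs_cds = observed_count(span_seq, motif, mask=cds_mask_full)
        exp_whole = expected_count(motif, len(span_seq), at_content)
        exp_cds = {v: 0.0 for v in motif.variants}
        for s, e in gene.cds:
            frag = expected_count(motif, e - s, at_content)
            for v in motif.variants:
                exp_cds[v] += frag[v]
        exp_rr = {v: 0.0 for v in motif.variants}
        for s, e in gene.regulatory:
            frag = expected_count(motif, e - s, at_content)
            for v in motif.variants:
                exp_rr[v] += frag[v]

        for variant in motif.variants:
            label = motif.variant_label(variant)
            obs_rr_v = obs_whole[variant] - obs_cds[variant]
            for region, obs, exp in (
                ("whole", obs_whole[variant], exp_whole[variant]),
                ("CDS", obs_cds[variant], exp_cds[variant]),
                ("RR", obs_rr_v, exp_rr[variant]),
            ):
                region_len = {
                    "whole": span_e - span_s,
                    "CDS": gene.cds_length,
                    "RR": gene.regulatory_length,
                }[region]
                ratio = obs / exp if (exp > 0 and region_len > 0) else np.nan
                rows.append(
                    {
                        "gene": gene.gene_id,
                        "region": region,
                        "motif_class": cls_name,
                        "variant": label,
                        "observed": obs,
                        "expected": exp,
                        "ratio": ratio,
                    }
                )
    return pd.DataFrame(rows)


def write_enrichment_tsv(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(table.columns) + "\n")
        table.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")
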