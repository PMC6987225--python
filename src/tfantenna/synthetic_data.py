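"""Generators for every input the pipeline consumes.

Random sequences with controlled A/T content (Drosophila-like 57% by
default), G/C-rich and declustered construct designs, antenna-like gene
architectures with annotations, noisy K_D titration tables produced by
the forward binding model, and noisy FCS decay sets.  Every generator is
a pure function of its configuration and an integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from tfantenna.binding_model import EnergyModelParams, landscape
from tfantenna.fcs_model import (
    FCSDecay,
    FCSModelParams,
    bound_fraction,
    default_lag_grid,
    simulate_decay,
)
from tfantenna.param_fitting import TitrationRecord
from tfantenna.sequence_io import GeneModel, SequenceRecord, SequenceError

logger = logging.getLogger(__name__)

DROSOPHILA_AT = 0.57


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def random_sequence(length: int, at_content: float = DROSOPHILA_AT, seed: int = 0,
                    seq_id: str | None = None) -> SequenceRecord:
    """I.i.d. bases with P(A)=P(T)=at/2 and P(G)=P(C)=(1-at)/2."""
    if not 0.0 <= at_content <= 1.0:
        raise ValueError("at_content must be in [0, 1]")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    probs = [at_content / 2, (1 - at_content) / 2, (1 - at_content) / 2, at_content / 2]
    bases = "".join(rng.choice(list("ACGT"), size=length, p=probs))
    return SequenceRecord(id=seq_id or f"rand_{length}_{seed}", bases=bases)


def gc_rich_sequence(length: int, seed: int = 0, seq_id: str | None = None) -> SequenceRecord:
    """Markov-generated G/C-rich sequence with no two consecutive A/T bases.

    After a G/C the next base is G/C with probability 0.82 (else A/T);
    after an A/T the next base is G/C with probability 1.  Within each
    class the two bases are equiprobable.  The first base follows the
    post-G/C rule.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    prev_at = False
    for _ in range(length):
        if prev_at:
            gc = True
        else:
            gc = rng.random() < 0.82
        if gc:
            out.append("G" if rng.random() < 0.5 else "C")
            prev_at = False
        else:
            out.append("A" if rng.random() < 0.5 else "T")
            prev_at = True
    return SequenceRecord(id=seq_id or f"gcrich_{length}_{seed}", bases="".join(out))


def decluster_sequence(
    composition: dict[str, int], seed: int = 0, max_run: int = 2,
    max_tries: int = 10_000, seq_id: str | None = None,
) -> SequenceRecord:
    """Random permutation of an exact base multiset avoiding long runs.

    Rejection-samples permutations until no homo-nucleotide run exceeds
    ``max_run``; the composition is preserved exactly.  Raises after
    ``max_tries`` rejections (infeasible compositions such as all-A).
    """
    pool = []
    for base, count in composition.items():
        if base not in "ACGT":
            raise SequenceError(f"invalid base {base!r} in composition")
        if count < 0:
            raise ValueError("counts must be non-negative")
        pool.extend(base * count)
    if not pool:
        raise ValueError("empty composition")
    arr = np.array(pool)
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        rng.shuffle(arr)
        seq = "".join(arr)
        run = 1
        ok = True
        for i in range(1, len(seq)):
            run = run + 1 if seq[i] == seq[i - 1] else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return SequenceRecord(id=seq_id or f"declust_{seed}", bases=seq)
    raise RuntimeError(
        f"no permutation without runs > {max_run} found in {max_tries} tries"
    )


def implant_sites(
    record: SequenceRecord, sites: list[tuple[int, str]]
) -> SequenceRecord:
    """Substitute hexamers at given 0-based positions; length preserved.

    Sites must be non-overlapping and within bounds.
    """
    occupied: list[tuple[int, int]] = []
    bases = list(record.bases)
    for pos, hexamer in sorted(sites):
        end = pos + len(hexamer)
        if pos < 0 or end > len(bases):
            raise SequenceError(f"site at {pos} out of bounds for {record.id!r}")
        for s, e in occupied:
            if pos < e and s < end:
                raise SequenceError(f"overlapping implant sites at {pos} and {s}")
        occupied.append((pos, end))
        bases[pos:end] = hexamer
    return SequenceRecord(id=record.id, bases="".join(bases))


@dataclass
class SyntheticGeneConfig:
    """Layout of an antenna-like synthetic gene.

    The extended span is [0, total_length); the transcript occupies the
    span minus ``flank`` on each side; ``cds_intervals`` (record
    coordinates) are drawn A/T-poor with no implanted sites, everything
    else A/T-rich with implanted degenerate-site clusters.
    """

    total_length: int = 7000
    flank: int = 2000
    cds_intervals: list[tuple[int, int]] = field(
        default_factory=lambda: [(2300, 3100), (3600, 4400)]
    )
    rr_at_content: float = DROSOPHILA_AT
    cds_at_content: float = 0.40
    implanted_sites: list[tuple[int, str]] | None = None  # None -> default clusters
    seed: int = 0
    gene_id: str = "syngene"

    def default_implants(self) -> list[tuple[int, str]]:
        """Degenerate-consensus clusters in the regulatory regions.

        The hexamer mix spans quintet-class (five consecutive consensus
        bases) and quartet-class (isolated core tetrad / shifted quartet)
        sites so that both classes are enriched in the RR by construction.
        """
        hexamers = ["TAATTG", "TAATTT", "CAATTG", "CAATTC", "GCATTA", "CTAATC"]
        cds = sorted(self.cds_intervals)
        sites = []
        rng = np.random.default_rng(self.seed + 1)
        # cluster positions inside regulatory segments, 12 bp apart
        rr_segments = []
        cursor = 0
        for s, e in cds:
            if s > cursor:
                rr_segments.append((cursor, s))
            cursor = e
        if cursor < self.total_length:
            rr_segments.append((cursor, self.total_length))
        for s, e in rr_segments:
            if e - s < 120:
                continue
            n_sites = min(16, (e - s - 20) // 12)
            start = s + 10
            for i in range(n_sites):
                pos = start + 12 * i
                sites.append((pos, str(rng.choice(hexamers))))
        return sites


def synthetic_gene(config: SyntheticGeneConfig) -> tuple[SequenceRecord, GeneModel]:
    """Generate an antenna-like gene sequence and its matching annotation."""
    cfg = config
    cds = sorted(cfg.cds_intervals)
    for s, e in cds:
        if s < cfg.flank or e > cfg.total_length - cfg.flank:
            raise SequenceError("CDS intervals must lie within the transcript region")
    rng_seeds = derive_seeds(cfg.seed, 2 + len(cds))
    # regulatory background
    rr = random_sequence(cfg.total_length, cfg.rr_at_content, rng_seeds[0]).bases
    bases = list(rr)
    for i, (s, e) in enumerate(cds):
        chunk = random_sequence(e - s, cfg.cds_at_content, rng_seeds[1 + i]).bases
        bases[s:e] = chunk
    record = SequenceRecord(id=cfg.gene_id, bases="".join(bases))

    sites = cfg.implanted_sites
    if sites is None:
        sites = cfg.default_implants()
    cds_set = cds
    for pos, hexamer in sites:
        for s, e in cds_set:
            if pos < e and s < pos + len(hexamer):
                raise SequenceError(f"implant at {pos} overlaps CDS [{s},{e})")
    record = implant_sites(record, sites)

    gene = GeneModel(
        gene_id=cfg.gene_id,
        seq_ref=cfg.gene_id,
        span=(0, cfg.total_length),
        cds=cds,
        exons=cds,  # exon structure beyond CDS is not modelled here
        strand="+",
    )
    return record, gene


def write_gene_gff3(gene: GeneModel, path) -> None:
    """Emit a minimal GFF3 (gene/mRNA/exon/CDS) for a synthetic gene.

    The transcript is the span minus nothing (the reader re-pads with its
    own flank); coordinates convert to 1-based inclusive.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        s, e = gene.span
        gid = gene.gene_id
        fh.write(
            f"{gene.seq_ref}\tsyn\tgene\t{s + 1}\t{e}\t.\t{gene.strand}\t.\tID={gid}\n"
        )
        fh.write(
            f"{gene.seq_ref}\tsyn\tmRNA\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
            f"ID={gid}.t1;Parent={gid}\n"
        )
        for xs, xe in gene.exons:
            fh.write(
                f"{gene.seq_ref}\tsyn\texon\t{xs + 1}\t{xe}\t.\t{gene.strand}\t.\t"
                f"Parent={gid}.t1\n"
            )
        for cs, ce in gene.cds:
            fh.write(
                f"{gene.seq_ref}\tsyn\tCDS\t{cs + 1}\t{ce}\t.\t{gene.strand}\t0\t"
                f"Parent={gid}.t1\n"
            )


def synthetic_titration_table(
    constructs: list[SequenceRecord],
    params: EnergyModelParams | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    ionic_strengths: list[float] | None = None,
) -> list[TitrationRecord]:
    """Noisy K_D table from the forward binding model.

    The true K_D of each construct comes from :func:`landscape` at the
    construct's ionic strength; the reported value is multiplied by
    ``10**eps`` with ``eps ~ Normal(0, noise_sd)`` (log10 units), and
    ``noise_sd`` is recorded as the uncertainty.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    params = params or EnergyModelParams()
    if ionic_strengths is None:
        ionic_strengths = [params.ionic_strength] * len(constructs)
    if len(ionic_strengths) != len(constructs):
        raise ValueError("one ionic strength per construct required")
    rng = np.random.default_rng(seed)
    records = []
    for rec, ionic in zip(constructs, ionic_strengths):
        p = params.with_(ionic_strength=ionic)
        kd_true = landscape(rec, p).kd
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        records.append(
            TitrationRecord(
                construct_id=f"{rec.id}@I={ionic:g}",
                seq_ref=rec.id,
                ionic_strength=ionic,
                kd=kd_true * 10.0**eps,
                sigma_log10=noise_sd if noise_sd > 0 else 1e-6,
            )
        )
    return records


def synthetic_fcs_titration(
    kd: float,
    conc_grid: list[float],
    fcs_params: FCSModelParams | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_grid: np.ndarray | None = None,
) -> list[FCSDecay]:
    """Per-concentration decays with P_prot set by the binding isotherm."""
    fcs_params = fcs_params or FCSModelParams()
    if t_grid is None:
        t_grid = default_lag_grid()
    seeds = derive_seeds(seed, len(conc_grid))
    decays = []
    for conc, s in zip(conc_grid, seeds):
        p = fcs_params.with_(p_prot=bound_fraction(conc, kd))
        decays.append(
            simulate_decay(p, t_grid, noise_sd=noise_sd, seed=s, dna_conc=conc)
        )
    return decays


# ---------------------------------------------------------------------------
# Construct-layout fixtures for the tandem-repeat designs used in binding
# experiments on long DNAs.  These are documented fixtures, not general
# operations: a 300-bp design brackets a central high-affinity site with one
# 150-bp core copy split around it plus XhoI/HindIII ends; the 600-bp design
# uses an NcoI end, AAAGACAAA linkers and two extra tandem copies.

XHOI = "CTCGAG"
NCOI = "CCATGG"
HINDIII = "AAGCTT"
LINKER = "AAAGACAAA"


def tandem_300bp(core150: SequenceRecord, site: str = "TAATTG") -> SequenceRecord:
    """Tandem layout bracketing one high-affinity site with two core copies.

    Element order: XhoI site, core segment with its high-affinity site and
    last three bases removed, a single copy of ``site``, a second
    site-stripped core copy, HindIII site.  The exact total length depends
    on the core sequence; with a 150-bp core carrying one site it is 300 bp.
    """
    if core150.n != 150:
        raise SequenceError("core must be 150 bp")
    stripped = core150.bases.replace(site, "", 1)[:-3]
    seq = XHOI + stripped + site + stripped + HINDIII
    return SequenceRecord(id=f"{core150.id}_300", bases=seq)


def tandem_600bp(core150: SequenceRecord, site: str = "TAATTG") -> SequenceRecord:
    """Longer tandem layout with linkers and two extra core copies.

    Element order: NcoI site, site-stripped core, AAAGACAAA linker, a
    single copy of ``site``, two tandem site-stripped core copies, linker,
    HindIII site.
    """
    if core150.n != 150:
        raise SequenceError("core must be 150 bp")
    stripped = core150.bases.replace(site, "", 1)
    seq = NCOI + stripped + LINKER + site + stripped + stripped + LINKER + HINDIII
    return SequenceRecord(id=f"{core150.id}_600", bases=seq)
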