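"""Partition-function model of TF binding to every 6-bp window of a duplex.

A DNA molecule of N base pairs offers 2*(N-5) potential 6-bp binding
sites, one set per strand, each read 5'->3' on its own strand.  Taking
the unbound protein as reference state (statistical weight 1), the
partition function at total DNA concentration [DNA] is

    Q = 1 + [DNA] * w0 * S,      S = sum_x exp(-dG_x / RT)

where dG_x is the binding free energy of site x and w0 is the ratio of
the diffusion-limited association rate constant to the interaction-free
dissociation rate constant.  The global dissociation constant is the DNA
concentration at which the protein is half bound (Q = 2):

    K_D = 1 / (w0 * S).

Two site energetics are implemented.  The *structure* variant decomposes
dG_x into electrostatic backbone contacts (Debye-Hueckel screened),
specific contacts to consensus core-tetrad bases, degenerate contacts to
any other A/T, and a cooperative term switched on by (near-)complete
consensus sites.  The *pwm* variant scores each base against a position
weight matrix, dG_k = -RT ln(p_k^B / 0.25), plus the same electrostatic
term and no cooperativity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from tfantenna.sequence_io import (
    SequenceRecord,
    SequenceError,
    iter_windows,
    reverse_complement,
)

logger = logging.getLogger(__name__)

R_GAS = 8.314e-3  # kJ mol^-1 K^-1


@dataclass(frozen=True)
class EnergyModelParams:
    """Energetic constants of the structure-based site model.

    Free energies are in kJ/mol; the defaults are the globally fitted
    values for the Engrailed homeodomain.  ``dg_elec0`` is the zero-ionic-
    strength Debye-Hueckel prefactor of the per-contact electrostatic
    interaction, screened as ``dg_elec0 * exp(-sqrt(I))`` with the ionic
    strength ``I`` in mol/L.  ``n_elec_central`` is the number of backbone
    contacts of a centrally located site (sites within ``end_margin`` bp of
    either DNA end lose one contact); the alternative ``elec_contacts =
    "extended"`` mode uses 8 central / 7 end contacts.
    """

    dg_consensus_core: float = -3.53
    dg_degenerate_at: float = -1.75
    dg_cp: float = -3.91
    dg_elec0: float = -8.18
    w0: float = 5e-4  # 1/M
    n_elec_central: int = 6
    elec_contacts: str = "standard"  # "standard" (6/5) or "extended" (8/7)
    temperature: float = 297.0  # K
    ionic_strength: float = 0.0  # mol/L
    consensus: str = "TAATTA"
    end_margin: int = 10  # bp, "less than 1 turn from either DNA end"

    def __post_init__(self) -> None:
        if self.w0 <= 0:
            raise ValueError("w0 must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")
        if len(self.consensus) != 6:
            raise ValueError("consensus must be a hexamer")
        if self.elec_contacts not in ("standard", "extended"):
            raise ValueError("elec_contacts must be 'standard' or 'extended'")
        if self.elec_contacts == "extended" and self.n_elec_central != 8:
            object.__setattr__(self, "n_elec_central", 8)
            logger.info("extended electrostatic mode: using 8 central / 7 end contacts")

    @property
    def rt(self) -> float:
        """RT in kJ/mol (~2.469 at 297 K)."""
        return R_GAS * self.temperature

    def with_(self, **kwargs) -> "EnergyModelParams":
        return replace(self, **kwargs)


def ionic_strength_from_nacl(nacl_m: float, buffer_contribution: float = 0.01) -> float:
    """Total ionic strength (mol/L) of a NaCl solution plus a fixed buffer term."""
    if nacl_m < 0:
        raise ValueError("NaCl molarity must be non-negative")
    return nacl_m + buffer_contribution


@dataclass
class PWMMatrix:
    """A 6 x 4 position weight matrix of base probabilities.

    ``probs[k, b]`` is the probability of base ``ACGT``[b] at motif
    position k (0-based).  A pseudo-count is added and columns renormalized
    on construction so every entry is strictly positive.
    """

    probs: np.ndarray
    pseudo_count: float = 1e-3

    BASES = "ACGT"

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (6, 4):
            raise ValueError(f"PWM must be 6x4, got {p.shape}")
        if np.any(p < 0):
            raise ValueError("PWM probabilities must be non-negative")
        p = p + self.pseudo_count
        p = p / p.sum(axis=1, keepdims=True)
        self.probs = p
        assert np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9)

    @classmethod
    def uniform(cls) -> "PWMMatrix":
        return cls(np.full((6, 4), 0.25), pseudo_count=0.0)

    @classmethod
    def from_consensus(cls, consensus: str, p_match: float = 0.85) -> "PWMMatrix":
        """A sharp synthetic PWM concentrated on a consensus hexamer."""
        p = np.full((6, 4), (1 - p_match) / 3)
        for k, b in enumerate(consensus):
            p[k, cls.BASES.index(b)] = p_match
        return cls(p)

    @classmethod
    def from_file(cls, path: str | Path, pseudo_count: float = 1e-3) -> "PWMMatrix":
        """Read a JASPAR-style tab matrix: 4 rows labelled A/C/G/T, 6 columns."""
        rows: dict[str, list[float]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith((">", "#")):
                    continue
                parts = line.replace("[", " ").replace("]", " ").split()
                base = parts[0].upper()
                if base not in cls.BASES:
                    raise ValueError(f"unexpected PWM row label {parts[0]!r}")
                rows[base] = [float(x) for x in parts[1:]]
        if set(rows) != set(cls.BASES):
            raise ValueError("PWM file must contain exactly the rows A, C, G, T")
        mat = np.array([rows[b] for b in cls.BASES], dtype=float).T  # -> 6x4
        if mat.shape != (6, 4):
            raise ValueError(f"PWM file must give 6 positions, got {mat.shape[0]}")
        sums = mat.sum(axis=1, keepdims=True)
        return cls(mat / sums, pseudo_count=pseudo_count)

    def prob(self, k: int, base: str) -> float:
        return float(self.probs[k, self.BASES.index(base)])


@dataclass(frozen=True)
class SiteEnergy:
    """One 6-bp binding site with its energy decomposition."""

    position: int  # 0-based first base, forward-frame coordinates
    strand: str  # "+" or "-"
    hexamer: str  # read 5'->3' on the site's own strand
    delta_central: int  # 1 for centrally located sites, 0 near ends
    delta_15: int
    delta_26: int
    delta_16: int
    dg_binding: float  # kJ/mol
    n_core: int
    n_deg_at: int
    n_elec: int
    coop_coeff: float


@dataclass
class BindingLandscape:
    """Per-site free energies over both strands plus global quantities."""

    seq_ref: str
    variant: str
    sites: list[SiteEnergy]
    weight_sum: float  # S = sum_x exp(-dG_x / RT), dimensionless
    kd: float  # global dissociation constant, mol/L
    params: EnergyModelParams

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (1-based start positions, field convention)."""
        return pd.DataFrame(
            {
                "strand": [s.strand for s in self.sites],
                "start_1based": [s.position + 1 for s in self.sites],
                "hexamer": [s.hexamer for s in self.sites],
                "dG_kJ_mol": [s.dg_binding for s in self.sites],
            }
        )


@dataclass
class OccupancyProfile:
    """Per-site occupancies at a given total DNA concentration."""

    dna_conc: float  # mol/L
    p_site: np.ndarray  # aligned with landscape.sites
    p_bound: float
    p_free: float


def electrostatic_energy(params: EnergyModelParams, is_central: bool) -> float:
    """Screened electrostatic backbone energy of one site, kJ/mol.

    ``n_contacts * dg_elec0 * exp(-sqrt(I))`` with one fewer contact for
    sites near either DNA end.
    """
    if params.ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    n = params.n_elec_central if is_central else params.n_elec_central - 1
    return n * params.dg_elec0 * math.exp(-math.sqrt(params.ionic_strength))


def specific_energy(
    hexamer: str, params: EnergyModelParams
) -> tuple[float, int, int, float]:
    """Specific + cooperative free energy of a hexamer site.

    Returns ``(dG_specific, n_core, n_deg_at, coop_coeff)``.  A base
    matching the consensus core tetrad (positions 2-5 of TAATTA)
    contributes ``dg_consensus_core``; any other A or T (including the
    flanking positions 1 and 6) contributes ``dg_degenerate_at``; G/C
    contributes nothing.  The cooperative coefficient is
    ``d16 + (d15 + d26)/2`` where d16/d15/d26 flag a full-consensus site
    or one matching the first/last five consensus bases; it multiplies
    ``dg_cp``.
    """
    if len(hexamer) != 6:
        raise SequenceError(f"site must be a hexamer, got {len(hexamer)} bases")
    cons = params.consensus
    n_core = 0
    n_deg = 0
    for k, b in enumerate(hexamer):
        if 1 <= k <= 4 and b == cons[k]:
            n_core += 1
        elif b in "AT":
            n_deg += 1
    d15 = int(hexamer[:5] == cons[:5])
    d26 = int(hexamer[1:] == cons[1:])
    d16 = int(hexamer == cons)
    coop = d16 + (d15 + d26) / 2.0
    dg = (
        n_core * params.dg_consensus_core
        + n_deg * params.dg_degenerate_at
        + coop * params.dg_cp
    )
    return dg, n_core, n_deg, coop


def pwm_site_energy(hexamer: str, pwm: PWMMatrix, params: EnergyModelParams) -> float:
    """PWM specific energy: sum_k -RT ln(p_k^B / 0.25), no cooperativity."""
    if len(hexamer) != 6:
        raise SequenceError(f"site must be a hexamer, got {len(hexamer)} bases")
    rt = params.rt
    dg = 0.0
    for k, b in enumerate(hexamer):
        p = pwm.prob(k, b)
        if p <= 0:
            raise ValueError(f"zero PWM probability for base {b} at position {k + 1}")
        dg += -rt * math.log(p / 0.25)
    return dg


def _enumerate_sites(record: SequenceRecord, params: EnergyModelParams):
    """Yield (position, strand, hexamer, own_strand_start_1based) for all sites.

    Positions are forward-frame 0-based.  The reverse-strand site covering
    forward window [i, i+6) starts, on its own strand read 5'->3', at
    1-based position N - i - 5.
    """
    n = record.n
    rc = reverse_complement(record.bases)
    for i, hexamer in iter_windows(record, 6):
        yield i, "+", hexamer, i + 1
    for i in range(n - 5):
        # rc[j:j+6] corresponds to forward window starting at n-6-j
        j = n - 6 - i
        yield i, "-", rc[j : j + 6], j + 1


def _is_central(own_start_1based: int, n: int, end_margin: int) -> bool:
    """Centrality of a site from its own-strand 1-based first-base position.

    The end-effect boundary is inclusive: a site starting at exactly
    ``end_margin`` (or ``N - end_margin``) counts as an end site.
    """
    return end_margin < own_start_1based < n - end_margin


def landscape(
    record: SequenceRecord,
    params: EnergyModelParams | None = None,
    variant: str = "structure",
    pwm: PWMMatrix | None = None,
) -> BindingLandscape:
    """Enumerate all 2*(N-5) sites and compute the binding landscape."""
    params = params or EnergyModelParams()
    if record.n < 6:
        raise SequenceError(f"sequence {record.id!r} shorter than 6 bp")
    if variant not in ("structure", "pwm"):
        raise ValueError(f"unknown model variant {variant!r}")
    if variant == "pwm" and pwm is None:
        raise ValueError("pwm variant requires a PWMMatrix")

    n = record.n
    rt = params.rt
    n_central = params.n_elec_central
    sites: list[SiteEnergy] = []
    for pos, strand, hexamer, own_start in _enumerate_sites(record, params):
        central = _is_central(own_start, n, params.end_margin)
        e_elec = electrostatic_energy(params, central)
        if variant == "structure":
            dg_spec, n_core, n_deg, coop = specific_energy(hexamer, params)
        else:
            dg_spec = pwm_site_energy(hexamer, pwm, params)
            n_core = n_deg = 0
            coop = 0.0
        cons = params.consensus
        d15 = int(hexamer[:5] == cons[:5])
        d26 = int(hexamer[1:] == cons[1:])
        d16 = int(hexamer == cons)
        sites.append(
            SiteEnergy(
                position=pos,
                strand=strand,
                hexamer=hexamer,
                delta_central=int(central),
                delta_15=d15,
                delta_26=d26,
                delta_16=d16,
                dg_binding=e_elec + dg_spec,
                n_core=n_core,
                n_deg_at=n_deg,
                n_elec=n_central if central else n_central - 1,
                coop_coeff=coop,
            )
        )
    energies = np.array([s.dg_binding for s in sites])
    weight_sum = float(np.exp(-energies / rt).sum())
    kd = 1.0 / (params.w0 * weight_sum)
    return BindingLandscape(
        seq_ref=record.id,
        variant=variant,
        sites=sites,
        weight_sum=weight_sum,
        kd=kd,
        params=params,
    )


def occupancy(scape: BindingLandscape, dna_conc: float) -> OccupancyProfile:
    """Per-site occupancy probabilities at total DNA concentration [DNA].

    Q = 1 + [DNA] * w0 * S;  p_x = w_x / Q;  p_free = 1/Q;
    p_bound = (Q-1)/Q.  At [DNA] = K_D the protein is half bound.
    """
    if dna_conc <= 0:
        raise ValueError("DNA concentration must be positive")
    params = scape.params
    rt = params.rt
    energies = np.array([s.dg_binding for s in scape.sites])
    w = params.w0 * dna_conc * np.exp(-energies / rt)
    q = 1.0 + w.sum()
    return OccupancyProfile(
        dna_conc=dna_conc, p_site=w / q, p_bound=(q - 1.0) / q, p_free=1.0 / q
    )


def segment_kd_profile(
    record: SequenceRecord,
    params: EnergyModelParams | None = None,
    variant: str = "structure",
    pwm: PWMMatrix | None = None,
    window: int = 75,
) -> pd.DataFrame:
    """Global K_D of consecutive non-overlapping segments along a sequence.

    A trailing remainder shorter than ``window`` (but at least 6 bp) is
    profiled at its true length and flagged ``partial``.
    """
    params = params or EnergyModelParams()
    if window < 6:
        raise ValueError("segment window must be at least 6 bp")
    if record.n < window:
        raise SequenceError(
            f"sequence {record.id!r} ({record.n} bp) shorter than window {window}"
        )
    rows = []
    for start in range(0, record.n, window):
        seg = record.bases[start : start + window]
        if len(seg) < 6:
            logger.warning(
                "segment at %d of %r is %d bp (<6), skipped", start, record.id, len(seg)
            )
            continue
        sub = SequenceRecord(id=f"{record.id}:{start}", bases=seg)
        kd = landscape(sub, params, variant, pwm).kd
        rows.append(
            {
                "segment_start": start,
                "segment_length": len(seg),
                "partial": len(seg) < window,
                "kd_M": kd,
                "log10_kd": math.log10(kd),
            }
        )
    return pd.DataFrame(rows)


def batch_kd(
    records: list[SequenceRecord],
    params: EnergyModelParams | None = None,
    variant: str = "structure",
    pwm: PWMMatrix | None = None,
    hist_bin_width: float = 0.25,
) -> tuple[pd.DataFrame, tuple[np.ndarray, np.ndarray] | None]:
    """Global K_D per record plus a log10(M) histogram of the batch.

    Per-record failures are logged and listed in the table (kd_M = NaN)
    without aborting the batch.  Returns ``(table, (counts, bin_edges))``;
    the histogram is ``None`` for an empty batch.
    """
    params = params or EnergyModelParams()
    rows = []
    for rec in records:
        try:
            kd = landscape(rec, params, variant, pwm).kd
            rows.append({"id": rec.id, "n_bp": rec.n, "kd_M": kd, "error": ""})
        except (SequenceError, ValueError) as exc:
            logger.error("record %r failed: %s", rec.id, exc)
            rows.append({"id": rec.id, "n_bp": rec.n, "kd_M": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows, columns=["id", "n_bp", "kd_M", "error"])
    if table.empty or table["kd_M"].dropna().empty:
        return table, None
    logs = np.log10(table["kd_M"].dropna().to_numpy())
    lo = math.floor(logs.min() / hist_bin_width) * hist_bin_width
    hi = math.ceil(logs.max() / hist_bin_width) * hist_bin_width + hist_bin_width / 2
    edges = np.arange(lo, hi + hist_bin_width, hist_bin_width)
    counts, edges = np.histogram(logs, bins=edges)
    return table, (counts, edges)


def site_feature_matrix(
    record: SequenceRecord, params: EnergyModelParams
) -> np.ndarray:
    """Per-site feature matrix for linear-in-parameters energy evaluation.

    Columns: (n_core, n_deg_at, coop_coeff, n_elec).  The structure-model
    site energy is then ``F @ (dGc, dGd, dGcp, dGe0 * exp(-sqrt(I)))``,
    which the global fitter exploits; it is numerically identical to the
    per-site path in :func:`landscape`.
    """
    n = record.n
    feats = np.empty((2 * (n - 5), 4))
    for idx, (pos, strand, hexamer, own_start) in enumerate(
        _enumerate_sites(record, params)
    ):
        central = _is_central(own_start, n, params.end_margin)
        _, n_core, n_deg, coop = specific_energy(hexamer, params)
        n_elec = params.n_elec_central if central else params.n_elec_central - 1
        feats[idx] = (n_core, n_deg, coop, n_elec)
    return feats


def write_landscape_tsv(
    scape: BindingLandscape, path: str | Path, occ: OccupancyProfile | None = None
) -> None:
    """Write the landscape as TSV with a '#'-prefixed header line."""
    frame = scape.to_frame()
    if occ is not None:
        frame["occupancy"] = occ.p_site
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(frame.columns) + "\n")
        frame.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6e")
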