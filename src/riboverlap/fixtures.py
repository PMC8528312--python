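"""Seeded synthetic data: random CDSs, planted motifs, fluctuation counts.

Everything in this module regenerates bit-identically from (spec, seed), so
every other module is testable without downloading any real sequence. The
generator emulates the structural properties a designer cares about — valid
CDS anatomy, controllable codon usage, planted translation-initiation
motifs in alternate frames — not the full compositional statistics of real
genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from riboverlap.design import MotifSpec, match_motif
from riboverlap.seqcore import CDSRecord, CodonTable, STANDARD_TABLE, translate


class PlantError(ValueError):
    """The requested planted feature cannot be placed."""


def random_cds(
    length_codons: int,
    usage_bias: dict[str, float] | None = None,
    seed: int = 0,
    table: CodonTable = STANDARD_TABLE,
    cds_id: str = "synthetic",
) -> CDSRecord:
    """A random valid CDS: ATG start, stop-free body, TAA terminal stop.

    ``usage_bias`` maps codons to sampling weights for the body (uniform
    over the 61 sense codons by default). Reproducible for a fixed seed.
    """
    if length_codons < 3:
        raise ValueError("a CDS needs at least start, one body codon, and stop")
    rng = np.random.default_rng(seed)
    sense = list(table.sense_codons)
    if usage_bias:
        weights = np.array([usage_bias.get(c, 0.0) for c in sense], dtype=float)
        if weights.sum() <= 0:
            raise ValueError("usage_bias assigns no weight to any sense codon")
        weights /= weights.sum()
    else:
        weights = np.full(len(sense), 1.0 / len(sense))
    body = rng.choice(sense, size=length_codons - 2, p=weights)
    seq = "ATG" + "".join(body) + "TAA"
    return CDSRecord(id=cds_id, sequence=seq, source=f"fixtures:seed={seed}")


@dataclass(frozen=True)
class ExpectedCandidate:
    """The answer key a planted motif guarantees."""

    start_nt: int
    frame: int
    overlap_fraction: float
    sd_start: int
    spacer_len: int


def plant_motif(
    cds: CDSRecord,
    start_nt: int,
    frame: int,
    spec: MotifSpec = MotifSpec(),
    spacer: int | None = None,
) -> tuple[CDSRecord, ExpectedCandidate]:
    """Overwrite a CDS so a zero-edit motif exists at (start_nt, frame).

    The SD hexamer, spacer (filled with C) and start codon are written over
    whole codons, with C fill up to codon boundaries, leaving the CDS start
    and terminal stop intact. Verified after construction: the motif is
    present as written and the existing frame stays stop-free; an
    infeasible plant raises :class:`PlantError`.
    """
    L = len(cds)
    s = start_nt
    if frame not in (1, 2):
        raise PlantError("frame must be 1 or 2 (the new frame must differ)")
    if s % 3 != frame:
        raise PlantError(f"start_nt {s} is not in frame {frame}")
    if s + 3 > L - 3:
        raise PlantError("no room: start codon would clobber the terminal stop")
    spacers = [spacer] if spacer is not None else list(
        range(spec.spacer_min, spec.spacer_max + 1)
    )
    sd = spec.sd_consensus
    start_codon = sorted(spec.start_codons)[0]
    for sp in spacers:
        sd_start = s - sp - len(sd)
        if sd_start < 3:
            continue
        seq = list(cds.sequence)
        region_start = (sd_start // 3) * 3
        region_end = -(-(s + 3) // 3) * 3
        for p in range(region_start, region_end):
            seq[p] = "C"
        for off, base in enumerate(sd):
            seq[sd_start + off] = base
        for off, base in enumerate(start_codon):
            seq[s + off] = base
        new_seq = "".join(seq)
        aa = translate(new_seq, 0)
        if "*" in aa[:-1]:
            continue  # frame-0 stop created; try another spacer
        placements = match_motif(new_seq, spec)
        if (sd_start, sp, s) not in placements:
            continue
        planted = CDSRecord(
            id=cds.id,
            sequence=new_seq,
            description=cds.description,
            source=f"{cds.source}+planted@{s}",
        )
        expected = ExpectedCandidate(
            start_nt=s,
            frame=frame,
            overlap_fraction=(L - s) / L,
            sd_start=sd_start,
            spacer_len=sp,
        )
        return planted, expected
    raise PlantError(
        f"cannot plant a motif with start at nt {s} in a {L}-nt CDS"
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible set of synthetic CDSs."""

    n_genes: int = 10
    length_codons: int = 60
    usage_bias: dict[str, float] | None = None
    plant_relative_position: float | None = None
    plant_frame: int = 1
    motif: MotifSpec = field(default_factory=MotifSpec)
    seed: int = 0


def generate_fixtures(spec: FixtureSpec):
    """List of (CDSRecord, ExpectedCandidate | None) per the spec."""
    out = []
    rng = np.random.default_rng(spec.seed)
    for i in range(spec.n_genes):
        sub = int(rng.integers(0, 2**31))
        cds = random_cds(
            spec.length_codons,
            usage_bias=spec.usage_bias,
            seed=sub,
            cds_id=f"synthetic_{i:04d}",
        )
        expected = None
        if spec.plant_relative_position is not None:
            L = len(cds)
            s = int(spec.plant_relative_position * L)
            s += (spec.plant_frame - s) % 3
            cds, expected = plant_motif(cds, s, spec.plant_frame, spec.motif)
        out.append((cds, expected))
    return out


def synth_fluctuation_counts(
    m_true: float,
    n_pops: int,
    plating_efficiency: float = 1.0,
    seed: int = 0,
    generations: int = 20,
) -> np.ndarray:
    """Luria-Delbrück mutant counts with expected mutation number m_true.

    Discrete synchronous generations: the expected number of mutational
    events per culture is spread over generations in proportion to the
    divisions occurring in each, and a clone founded in generation t grows
    to 2^(g - t) cells. Heavy-tailed (jackpot) counts arise from early
    mutations. Adequate for estimator testing, not a research-grade
    sampler (no phenotypic lag, no death, no post-plating growth).
    """
    if m_true < 0:
        raise ValueError("m_true must be >= 0")
    rng = np.random.default_rng(seed)
    g = generations
    divisions = 2.0 ** np.arange(g)  # divisions in generation t (t = 1..g)
    frac = divisions / divisions.sum()
    counts = np.zeros(n_pops, dtype=np.int64)
    for t in range(1, g + 1):
        events = rng.poisson(m_true * frac[t - 1], size=n_pops)
        counts += events * 2 ** (g - t)
    if plating_efficiency < 1.0:
        counts = rng.binomial(counts, plating_efficiency)
    return counts
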