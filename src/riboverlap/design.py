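"""Design of protective overlapping reading frames inside an existing CDS.

The designer opens a new reading frame inside a gene by creating a bacterial
translation-initiation motif — a Shine-Dalgarno (SD) hexamer, a 3-7 nt
spacer, then a start codon — in a frame shifted by +1 or +2 relative to the
gene, using only synonymous (or, at higher stringency, near-synonymous)
recoding of the existing frame. The new frame is then cleared of stop codons
and, best-effort, of competing start motifs, mononucleotide runs and rare
codons, so an essential gene can be expressed from it.

Creating a motif is a local problem: a placement constrains only the codons
its SD hexamer and start codon touch, and every such codon set fits inside
an 18-nt (6-codon) window. The search therefore enumerates recodings of
exactly those codons at each possible placement, which is equivalent to
brute-forcing all synonymous variants of a sliding 18-nt window but visits
only the combinations that can matter.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from riboverlap.seqcore import (
    STOP,
    CDSRecord,
    CodonTable,
    STANDARD_TABLE,
    SequenceError,
    edit_distance_aa,
    translate,
)


class Stringency(str, Enum):
    """Budget of non-synonymous changes in the existing gene.

    S0: none. S1: one in total (motif creation or stop removal).
    S2plus: one for the motif; stop codons that cannot be removed
    synonymously are reported as remaining manual substitutions instead of
    rejecting the candidate.
    """

    S0 = "S0"
    S1 = "S1"
    S2plus = "S2plus"


@dataclass(frozen=True)
class MotifSpec:
    """Definition of a translation-initiation motif.

    SD consensus AGGAGG with up to ``max_sd_mismatches`` substitutions
    (plain Hamming distance, no thermodynamics), followed by a
    ``spacer_min``..``spacer_max`` nt spacer, followed by a start codon.
    """

    sd_consensus: str = "AGGAGG"
    max_sd_mismatches: int = 1
    spacer_min: int = 3
    spacer_max: int = 7
    start_codons: frozenset[str] = frozenset({"ATG"})
    window_nt: int = 18

    def __post_init__(self) -> None:
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min > spacer_max")
        min_window = len(self.sd_consensus) + self.spacer_max + 3
        min_window += (-min_window) % 3
        if self.window_nt < min_window:
            raise ValueError(
                f"window_nt {self.window_nt} < minimal motif span {min_window}"
            )

    @property
    def min_motif_len(self) -> int:
        return len(self.sd_consensus) + self.spacer_min + 3


class EditPurpose(str, Enum):
    MOTIF_CREATION = "motif_creation"
    STOP_REMOVAL = "stop_removal"
    SECONDARY_START_REMOVAL = "secondary_start_removal"
    REPEAT_REMOVAL = "repeat_removal"
    RARE_CODON_REMOVAL = "rare_codon_removal"


@dataclass(frozen=True)
class Edit:
    """A single-nucleotide change to the existing gene."""

    position: int
    ref: str
    alt: str
    synonymous: bool
    purpose: EditPurpose

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt is not an edit")


class RejectionReason(str, Enum):
    IRREMOVABLE_STOP = "irremovable_stop"


@dataclass(frozen=True)
class Rejection:
    """A raw motif site that cannot be turned into a usable frame."""

    cds_id: str
    start_nt: int
    frame: int
    reason: RejectionReason


@dataclass(frozen=True)
class RawSite:
    """A motif placement found by the search, before frame clearing."""

    cds_id: str
    start_nt: int
    frame: int
    sd_start: int
    spacer_len: int
    sd_mismatches: int
    edits: tuple[tuple[int, str, str], ...]  # (position, ref, alt)
    aa_cost: int


@dataclass(frozen=True)
class RiboverlapCandidate:
    """One designed alternate reading frame inside an existing CDS."""

    cds_id: str
    start_nt: int
    frame: int
    edits: tuple[Edit, ...]
    overlap_fraction: float
    aa_changes_made: int
    aa_changes_remaining: int
    sd_mismatches: int
    spacer_len: int
    sd_start: int
    edited_sequence: str
    frame_stop_free: bool
    secondary_starts_cleared: bool
    repeats_cleared: bool
    rare_codons_cleared: bool
    #: per irremovable stop: (new-frame stop position,
    #: tuple of suggested (codon_index, replacement_codon))
    suggestions: tuple[tuple[int, tuple[tuple[int, str], ...]], ...] = ()

    @property
    def n_syn_edits(self) -> int:
        return sum(1 for e in self.edits if e.synonymous)


@dataclass(frozen=True)
class RibosorConfig:
    motif: MotifSpec = field(default_factory=MotifSpec)
    stringency: Stringency = Stringency.S0
    max_repeat_len: int = 3
    clear_rare_codons: bool = True
    clear_secondary_starts: bool = True
    table: CodonTable = field(default_factory=lambda: STANDARD_TABLE)


# ---------------------------------------------------------------------------
# motif matching (no recoding)


def match_motif(window: str, spec: MotifSpec = MotifSpec()) -> list[tuple[int, int, int]]:
    """All motif placements present in ``window`` as written.

    Returns (sd_start, spacer_len, start_pos) tuples, ascending by sd_start
    then spacer length. Positions are relative to the window start.
    """
    sd = spec.sd_consensus
    k = len(sd)
    out = []
    for sd_start in range(0, len(window) - spec.min_motif_len + 1):
        sub = window[sd_start : sd_start + k]
        mism = sum(a != b for a, b in zip(sub, sd))
        if mism > spec.max_sd_mismatches:
            continue
        for spacer in range(spec.spacer_min, spec.spacer_max + 1):
            start_pos = sd_start + k + spacer
            if start_pos + 3 > len(window):
                break
            if window[start_pos : start_pos + 3] in spec.start_codons:
                out.append((sd_start, spacer, start_pos))
    return out


# ---------------------------------------------------------------------------
# placement-driven recoding search


def _codon_option_classes(
    codon: str,
    hard: dict[int, str],
    soft: dict[int, str],
    table: CodonTable,
    allow_nonsyn: bool,
    frozen: bool,
) -> dict[tuple[int, int], tuple[int, str]]:
    """Best replacement codon per (SD-mismatch count, AA cost) class.

    ``hard`` maps codon offsets (0-2) to required bases (start codon);
    ``soft`` maps offsets to preferred bases (SD consensus). Returns
    {(mismatches, aa_cost): (nt_edits, codon)} keeping, per class, the
    option with fewest nucleotide edits, ties to the lexicographically
    smallest codon.
    """
    if frozen:
        options: Iterable[tuple[str, int]] = [(codon, 0)]
    else:
        syn = table.synonyms(codon)
        options = [(c, 0) for c in syn]
        if allow_nonsyn:
            syn_set = set(syn)
            options = list(options) + [
                (c, 1) for c in table.sense_codons if c not in syn_set
            ]
    best: dict[tuple[int, int], tuple[int, str]] = {}
    for cand, cost in options:
        ok = all(cand[off] == base for off, base in hard.items())
        if not ok:
            continue
        mism = sum(cand[off] != base for off, base in soft.items())
        edits = sum(a != b for a, b in zip(cand, codon))
        key = (mism, cost)
        val = (edits, cand)
        if key not in best or val < best[key]:
            best[key] = val
    return best


def _site_sort_key(site: RawSite) -> tuple:
    # minimum AA cost, then fewest nt edits, then lexicographically smallest
    # edited motif region, then earliest SD, shortest spacer
    edited = "".join(alt for _, _, alt in site.edits)
    return (
        site.aa_cost,
        len(site.edits),
        _edited_span(site),
        site.sd_start,
        site.spacer_len,
    )


def _edited_span(site: RawSite) -> str:
    return ",".join(f"{p}{a}" for p, _, a in site.edits)


def find_motif_sites(cds: CDSRecord, config: RibosorConfig) -> list[RawSite]:
    """Enumerate motif placements creatable within the stringency budget.

    For every alternate-frame start-codon position and spacer length, the
    codons overlapping the SD hexamer and the start codon are recoded
    (synonymously; at stringency >= S1 one codon may change amino acid) and
    the placement is kept if a start codon appears with an SD hexamer within
    the allowed Hamming distance. Per (start_nt, frame) only the best
    variant survives: minimum AA cost, then fewest nucleotide edits, then
    lexicographically smallest recoding.
    """
    seq = cds.sequence
    L = len(seq)
    spec = config.motif
    table = config.table
    sd = spec.sd_consensus
    k = len(sd)
    budget = 0 if config.stringency is Stringency.S0 else 1
    allow_nonsyn = budget > 0
    # the terminal stop codon (if present) is never recoded
    frozen_idx = cds.n_codons - 1 if cds.has_terminal_stop else -1

    best_per_start: dict[int, RawSite] = {}
    cache: dict[tuple, dict] = {}

    for s in range(spec.min_motif_len - 3, L - 2):
        if s % 3 == 0:
            continue
        for start_codon in sorted(spec.start_codons):
            for spacer in range(spec.spacer_min, spec.spacer_max + 1):
                sd_start = s - spacer - k
                if sd_start < 0:
                    continue
                # per-codon constraints
                constraints: dict[int, tuple[dict, dict]] = {}
                for off, base in enumerate(start_codon):
                    p = s + off
                    ci = p // 3
                    constraints.setdefault(ci, ({}, {}))[0][p % 3] = base
                for off, base in enumerate(sd):
                    p = sd_start + off
                    ci = p // 3
                    constraints.setdefault(ci, ({}, {}))[1][p % 3] = base
                classes = []
                feasible = True
                for ci in sorted(constraints):
                    hard, soft = constraints[ci]
                    codon = seq[3 * ci : 3 * ci + 3]
                    key = (
                        codon,
                        tuple(sorted(hard.items())),
                        tuple(sorted(soft.items())),
                        allow_nonsyn,
                        ci == frozen_idx,
                    )
                    if key not in cache:
                        cache[key] = _codon_option_classes(
                            codon, hard, soft, table, allow_nonsyn, ci == frozen_idx
                        )
                    cls = cache[key]
                    if not cls:
                        feasible = False
                        break
                    classes.append((ci, cls))
                if not feasible:
                    continue
                # choose one (mismatch, cost) class per codon
                best_combo = None
                for combo in itertools.product(
                    *[sorted(cls.items()) for _, cls in classes]
                ):
                    mism = sum(key[0] for key, _ in combo)
                    cost = sum(key[1] for key, _ in combo)
                    if mism > spec.max_sd_mismatches or cost > budget:
                        continue
                    edits = sum(val[0] for _, val in combo)
                    codons = tuple(val[1] for _, val in combo)
                    cand = (cost, edits, codons, mism)
                    if best_combo is None or cand < best_combo:
                        best_combo = cand
                if best_combo is None:
                    continue
                cost, _, codons, mism = best_combo
                edit_list = []
                for (ci, _), new_codon in zip(classes, codons):
                    old = seq[3 * ci : 3 * ci + 3]
                    for off in range(3):
                        if old[off] != new_codon[off]:
                            edit_list.append((3 * ci + off, old[off], new_codon[off]))
                site = RawSite(
                    cds_id=cds.id,
                    start_nt=s,
                    frame=s % 3,
                    sd_start=sd_start,
                    spacer_len=spacer,
                    sd_mismatches=mism,
                    edits=tuple(sorted(edit_list)),
                    aa_cost=cost,
                )
                prev = best_per_start.get(s)
                if prev is None or _site_sort_key(site) < _site_sort_key(prev):
                    best_per_start[s] = site
    return [best_per_start[s] for s in sorted(best_per_start)]


# ---------------------------------------------------------------------------
# frame clearing


def _frame_stops(seq: str, start_nt: int, table: CodonTable) -> list[int]:
    return [
        p
        for p in range(start_nt, len(seq) - 2, 3)
        if table.is_stop(seq[p : p + 3])
    ]


def _apply_codon(seq: list[str], ci: int, codon: str) -> list[tuple[int, str, str]]:
    changes = []
    for off in range(3):
        p = 3 * ci + off
        if seq[p] != codon[off]:
            changes.append((p, seq[p], codon[off]))
            seq[p] = codon[off]
    return changes


class _Clearer:
    """Working state for clearing one raw site's new reading frame."""

    def __init__(self, cds: CDSRecord, raw: RawSite, config: RibosorConfig):
        self.cds = cds
        self.raw = raw
        self.config = config
        self.table = config.table
        self.seq = list(cds.sequence)
        self.edits: list[Edit] = []
        self.aa_changes_made = 0
        self.aa_changes_remaining = 0
        self.suggestions: list[tuple[int, tuple[tuple[int, str], ...]]] = []
        self.frozen_idx = cds.n_codons - 1 if cds.has_terminal_stop else -1
        # motif nucleotides are frozen once created
        spec = config.motif
        self.protected = set(
            range(raw.sd_start, raw.sd_start + len(spec.sd_consensus))
        ) | set(range(raw.start_nt, raw.start_nt + 3))
        for pos, ref, alt in raw.edits:
            original = self.seq[pos]
            assert original == ref
            self.seq[pos] = alt
        self._record_raw_edits()

    def _record_raw_edits(self) -> None:
        orig = self.cds.sequence
        changed_codons = sorted({p // 3 for p, _, _ in self.raw.edits})
        nonsyn = set()
        for ci in changed_codons:
            old = orig[3 * ci : 3 * ci + 3]
            new = "".join(self.seq[3 * ci : 3 * ci + 3])
            if self.table.code[old] != self.table.code[new]:
                nonsyn.add(ci)
        for pos, ref, alt in self.raw.edits:
            self.edits.append(
                Edit(pos, ref, alt, pos // 3 not in nonsyn, EditPurpose.MOTIF_CREATION)
            )
        self.aa_changes_made = len(nonsyn)

    # -- generic constrained recoding -------------------------------------

    def _codon_options(self, ci: int, allow_nonsyn: bool) -> list[tuple[str, int]]:
        codon = "".join(self.seq[3 * ci : 3 * ci + 3])
        if ci == self.frozen_idx:
            return [(codon, 0)]
        opts = [(c, 0) for c in self.table.synonyms(codon)]
        if allow_nonsyn:
            syn = {c for c, _ in opts}
            opts += [(c, 1) for c in self.table.sense_codons if c not in syn]
        return opts

    def _touches_protected(self, ci: int, codon: str) -> bool:
        for off in range(3):
            p = 3 * ci + off
            if p in self.protected and self.seq[p] != codon[off]:
                return True
        return False

    def _best_fix(
        self,
        codon_indices: Sequence[int],
        predicate,
        allow_nonsyn: bool = False,
        max_cost: int = 0,
    ):
        """Best joint recoding of ``codon_indices`` satisfying ``predicate``.

        predicate(trial_seq_str) -> bool on the whole trial sequence.
        Returns (cost, [(ci, codon), ...]) or None. Ranking: AA cost, then
        nucleotide edits, then lexicographic on replacement codons.
        """
        option_lists = [self._codon_options(ci, allow_nonsyn) for ci in codon_indices]
        best = None
        for combo in itertools.product(*option_lists):
            cost = sum(c for _, c in combo)
            if cost > max_cost:
                continue
            if any(
                self._touches_protected(ci, codon)
                for ci, (codon, _) in zip(codon_indices, combo)
            ):
                continue
            nt_edits = 0
            trial = self.seq[:]
            changed = False
            for ci, (codon, _) in zip(codon_indices, combo):
                for off in range(3):
                    p = 3 * ci + off
                    if trial[p] != codon[off]:
                        trial[p] = codon[off]
                        nt_edits += 1
                        changed = True
            if not changed:
                continue
            if not predicate("".join(trial)):
                continue
            key = (cost, nt_edits, tuple(c for c, _ in combo))
            if best is None or key < best[0]:
                best = (key, [(ci, c) for ci, (c, _) in zip(codon_indices, combo)])
        if best is None:
            return None
        return best[0][0], best[1]

    def _commit(self, assignment, purpose: EditPurpose) -> None:
        orig = self.cds.sequence
        for ci, codon in assignment:
            old_aa = self.table.code["".join(self.seq[3 * ci : 3 * ci + 3])]
            changes = _apply_codon(self.seq, ci, codon)
            orig_aa = self.table.code[orig[3 * ci : 3 * ci + 3]]
            syn = self.table.code[codon] == orig_aa
            for p, ref, alt in changes:
                self.edits.append(Edit(p, ref, alt, syn, purpose))
            if not syn and old_aa == orig_aa:
                self.aa_changes_made += 1

    # -- stop removal ------------------------------------------------------

    def remove_stops(self) -> Rejection | None:
        s = self.raw.start_nt
        table = self.table
        budget_total = {
            Stringency.S0: 0,
            Stringency.S1: 1,
            Stringency.S2plus: 1,
        }[self.config.stringency]
        deferred: set[int] = set()
        while True:
            stops = [p for p in _frame_stops("".join(self.seq), s, table) if p not in deferred]
            if not stops:
                return None
            p = stops[0]
            c1, c2 = p // 3, (p + 2) // 3
            existing = set(_frame_stops("".join(self.seq), s, table))

            def ok(trial: str, _p=p, _existing=existing) -> bool:
                new_stops = set(_frame_stops(trial, s, table))
                return _p not in new_stops and new_stops <= _existing

            fix = self._best_fix([c1, c2], ok, allow_nonsyn=False, max_cost=0)
            if fix is not None:
                self._commit(fix[1], EditPurpose.STOP_REMOVAL)
                continue
            # no synonymous fix
            if self.config.stringency is Stringency.S1 and (
                self.aa_changes_made < budget_total
            ):
                fix = self._best_fix([c1, c2], ok, allow_nonsyn=True, max_cost=1)
                if fix is not None:
                    self._commit(fix[1], EditPurpose.STOP_REMOVAL)
                    continue
            if self.config.stringency is Stringency.S2plus:
                sugg = self._suggest_nonsyn_fixes(p, c1, c2, ok)
                self.aa_changes_remaining += 1
                self.suggestions.append((p, sugg))
                deferred.add(p)
                continue
            return Rejection(
                self.cds.id, s, self.raw.frame, RejectionReason.IRREMOVABLE_STOP
            )

    def _suggest_nonsyn_fixes(self, p, c1, c2, predicate):
        out = []
        for ci in (c1, c2):
            if ci == self.frozen_idx:
                continue
            current = "".join(self.seq[3 * ci : 3 * ci + 3])
            for alt in self.table.sense_codons:
                if alt == current or self.table.code[alt] == self.table.code[current]:
                    continue
                if self._touches_protected(ci, alt):
                    continue
                trial = self.seq[:]
                for off in range(3):
                    trial[3 * ci + off] = alt[off]
                if predicate("".join(trial)):
                    out.append((ci, alt))
        return tuple(out)

    # -- best-effort optimisation (synonymous only) ------------------------

    def _frame_ok(self, trial: str) -> bool:
        """No new stop codon in the new frame relative to the current state."""
        s = self.raw.start_nt
        return set(_frame_stops(trial, s, self.table)) <= set(
            _frame_stops("".join(self.seq), s, self.table)
        )

    def clear_secondary_starts(self) -> bool:
        spec = self.config.motif
        s = self.raw.start_nt
        for _ in range(3):  # bounded passes
            placements = [
                pl
                for pl in match_motif("".join(self.seq), spec)
                if pl[2] > s
            ]
            if not placements:
                return True
            progress = False
            for sd_start, spacer, start_pos in placements:
                span = sorted(
                    {q // 3 for q in range(sd_start, sd_start + len(spec.sd_consensus))}
                    | {q // 3 for q in range(start_pos, start_pos + 3)}
                )

                def broken(trial, _sd=sd_start, _sp=spacer, _st=start_pos):
                    if not self._frame_ok(trial):
                        return False
                    return (_sd, _sp, _st) not in match_motif(trial, spec)

                # try single-codon fixes first, then pairs along the span
                fix = None
                for ci in span:
                    fix = self._best_fix([ci], broken)
                    if fix:
                        break
                if fix is None and len(span) > 1:
                    fix = self._best_fix(span[:2], broken)
                if fix:
                    self._commit(fix[1], EditPurpose.SECONDARY_START_REMOVAL)
                    progress = True
                    break
            if not progress:
                break
        placements = [
            pl for pl in match_motif("".join(self.seq), spec) if pl[2] > s
        ]
        return not placements

    def _runs(self) -> list[tuple[int, int]]:
        """Mononucleotide runs longer than max_repeat_len in the overlap."""
        s = self.raw.start_nt
        seq = "".join(self.seq)
        runs = []
        i = s
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if j - i > self.config.max_repeat_len:
                runs.append((i, j))
            i = j
        return runs

    def clear_repeats(self) -> bool:
        for _ in range(5):
            runs = self._runs()
            if not runs:
                return True
            progress = False
            for a, b in runs:
                span = sorted({q // 3 for q in range(a, b)})

                def shorter(trial, _a=a, _b=b):
                    if not self._frame_ok(trial):
                        return False
                    base = trial[_a]
                    # the run must be broken below threshold somewhere inside
                    length = 1
                    worst = 1
                    for q in range(_a + 1, _b):
                        if trial[q] == trial[q - 1]:
                            length += 1
                        else:
                            length = 1
                        worst = max(worst, length)
                    first = 1
                    for q in range(_a + 1, _b):
                        if trial[q] == base:
                            first += 1
                        else:
                            break
                    del first
                    return worst <= self.config.max_repeat_len

                fix = None
                for ci in span:
                    fix = self._best_fix([ci], shorter)
                    if fix:
                        break
                if fix:
                    self._commit(fix[1], EditPurpose.REPEAT_REMOVAL)
                    progress = True
                    break
            if not progress:
                break
        return not self._runs()

    def clear_rare(self) -> bool:
        s = self.raw.start_nt
        table = self.table
        for _ in range(5):
            seq = "".join(self.seq)
            rare = [
                p
                for p in range(s, len(seq) - 2, 3)
                if seq[p : p + 3] in table.rare_codons
            ]
            if not rare:
                return True
            progress = False
            for p in rare:
                span = [p // 3, (p + 2) // 3]

                def fixed(trial, _p=p, _n=len(rare)):
                    if not self._frame_ok(trial):
                        return False
                    remaining = sum(
                        1
                        for q in range(s, len(trial) - 2, 3)
                        if trial[q : q + 3] in table.rare_codons
                    )
                    return trial[_p : _p + 3] not in table.rare_codons and remaining < _n

                fix = self._best_fix(sorted(set(span)), fixed)
                if fix:
                    self._commit(fix[1], EditPurpose.RARE_CODON_REMOVAL)
                    progress = True
                    break
            if not progress:
                break
        seq = "".join(self.seq)
        return not any(
            seq[p : p + 3] in table.rare_codons for p in range(s, len(seq) - 2, 3)
        )

    # -- assembly ----------------------------------------------------------

    def _net_edits(self, final: str) -> tuple[Edit, ...]:
        """Collapse the edit history to the net original→final differences.

        A position touched more than once keeps the purpose of the last
        step that changed it; positions reverted to the original vanish.
        The synonymous flag reflects the final codon versus the original.
        """
        orig = self.cds.sequence
        last_purpose = {e.position: e.purpose for e in self.edits}
        out = []
        for pos, (a, b) in enumerate(zip(orig, final)):
            if a == b:
                continue
            ci = pos // 3
            syn = (
                self.table.code[orig[3 * ci : 3 * ci + 3]]
                == self.table.code[final[3 * ci : 3 * ci + 3]]
            )
            out.append(Edit(pos, a, b, syn, last_purpose[pos]))
        return tuple(out)

    def result(self) -> RiboverlapCandidate:
        s = self.raw.start_nt
        sec = self.clear_secondary_starts() if self.config.clear_secondary_starts else False
        rep = self.clear_repeats()
        rare = self.clear_rare() if self.config.clear_rare_codons else False
        seq = "".join(self.seq)
        L = len(seq)
        stops = _frame_stops(seq, s, self.table)
        edits = self._net_edits(seq)
        return RiboverlapCandidate(
            cds_id=self.cds.id,
            start_nt=s,
            frame=self.raw.frame,
            edits=edits,
            overlap_fraction=(L - s) / L,
            aa_changes_made=edit_distance_aa(self.cds.sequence, seq, self.table),
            aa_changes_remaining=self.aa_changes_remaining,
            sd_mismatches=self.raw.sd_mismatches,
            spacer_len=self.raw.spacer_len,
            sd_start=self.raw.sd_start,
            edited_sequence=seq,
            frame_stop_free=not stops,
            secondary_starts_cleared=sec,
            repeats_cleared=rep,
            rare_codons_cleared=rare,
            suggestions=tuple(self.suggestions),
        )


def clear_frame(
    cds: CDSRecord, raw: RawSite, config: RibosorConfig
) -> RiboverlapCandidate | Rejection:
    """Remove stop codons from the new frame and tidy it best-effort.

    Stop removal recodes the <=2 existing-frame codons under each new-frame
    stop, synonymously first; at S1 one amino-acid change (shared with motif
    creation) may be spent, at S2plus irremovable stops become suggested
    manual substitutions. Then, without ever spending amino-acid changes:
    competing downstream start motifs, mononucleotide runs and rare codons
    in the new frame are removed where synonymous recoding allows.
    """
    clearer = _Clearer(cds, raw, config)
    rej = clearer.remove_stops()
    if rej is not None:
        return rej
    return clearer.result()


def design(cds: CDSRecord, config: RibosorConfig = RibosorConfig()) -> list[RiboverlapCandidate]:
    """Full pipeline: find motif sites, clear each frame, sort candidates.

    Candidates are sorted by ascending start position (descending overlap
    fraction — the longest overlaps protect best), then ascending
    amino-acid cost. Deterministic for fixed input and configuration.
    """
    out = []
    for raw in find_motif_sites(cds, config):
        res = clear_frame(cds, raw, config)
        if isinstance(res, RiboverlapCandidate):
            out.append(res)
    out.sort(
        key=lambda c: (c.start_nt, c.aa_changes_made + c.aa_changes_remaining)
    )
    return out


# ---------------------------------------------------------------------------
# construct assembly


@dataclass(frozen=True)
class Feature:
    start: int
    end: int
    label: str
    frame: int


@dataclass(frozen=True)
class Construct:
    """An assembled overlap construct: edited upstream gene, phasing pad,
    downstream gene body, with CDS feature annotations for both frames."""

    sequence: str
    features: tuple[Feature, ...]
    pad: str
    upstream_protein: str
    overlap_protein: str


def pad_length(upstream_len: int, start_nt: int) -> int:
    """Nucleotides needed after the upstream gene to phase the downstream CDS."""
    return (3 - ((upstream_len - start_nt) % 3)) % 3


def _pad_choices(k: int) -> list[str]:
    if k == 0:
        return [""]
    default = "GC"[:k] if k <= 2 else "GC" + "G" * (k - 2)
    rest = ["".join(p) for p in itertools.product("GCAT", repeat=k)]
    return [default] + [p for p in rest if p != default]


def apply_overlap(
    cds: CDSRecord,
    candidate: RiboverlapCandidate,
    downstream: CDSRecord,
    keep_downstream_start: bool = False,
    table: CodonTable = STANDARD_TABLE,
) -> Construct:
    """Clone a downstream gene into the candidate's reading frame.

    The construct is the edited upstream sequence, 0-2 phasing pad
    nucleotides, then the downstream CDS body (its own start codon dropped
    by default — initiation uses the created motif) and stop codon.
    Verifies that the upstream protein carries only the declared amino-acid
    changes, that translation from the created start runs stop-free through
    the junction and ends in the downstream protein, and that the pad
    creates neither a stop nor a new start motif.
    """
    if candidate.cds_id != cds.id:
        raise ValueError(
            f"candidate was designed for {candidate.cds_id!r}, not {cds.id!r}"
        )
    if candidate.aa_changes_remaining > 0:
        raise SequenceError(
            "candidate still has remaining manual substitutions; apply them first"
        )
    if not candidate.frame_stop_free:
        raise SequenceError("candidate's new frame still contains stop codons")
    upstream = candidate.edited_sequence
    L = len(upstream)
    s = candidate.start_nt
    body = downstream.sequence
    if not keep_downstream_start and body[:3] in ("ATG", "GTG", "TTG"):
        body = body[3:]
    if len(body) < 3 or not translate(body, 0, table).rstrip(STOP):
        raise SequenceError("downstream gene has no coding body")

    # (i) upstream protein unchanged except declared AA changes
    n_diff = edit_distance_aa(cds.sequence, upstream, table)
    if n_diff != candidate.aa_changes_made:
        raise SequenceError(
            f"upstream protein carries {n_diff} amino-acid changes, "
            f"candidate declares {candidate.aa_changes_made}"
        )

    k = pad_length(L, s)
    body_protein = translate(body, 0, table)
    spec = MotifSpec()
    last_error = None
    for pad in _pad_choices(k):
        construct = upstream + pad + body
        overlap_prot = translate(construct, s, table)
        internal = overlap_prot[:-1] if body_protein.endswith(STOP) else overlap_prot
        if STOP in internal:
            bad = internal.index(STOP) * 3 + s
            last_error = (
                f"stop codon at construct nt {bad} in the overlap frame"
            )
            continue
        if k and _pad_makes_motif(construct, L, k, spec):
            last_error = "pad creates a new start motif at the junction"
            continue
        ext = translate(construct[s : L + k], 0, table)
        assert overlap_prot == ext + body_protein
        features = (
            Feature(0, L, f"{cds.id} (existing frame)", 0),
            Feature(L, L + k, "phasing pad", -1) if k else None,
            Feature(
                s,
                len(construct),
                f"{downstream.id} riboverlap (frame +{candidate.frame})",
                candidate.frame,
            ),
        )
        return Construct(
            sequence=construct,
            features=tuple(f for f in features if f is not None),
            pad=pad,
            upstream_protein=translate(upstream, 0, table),
            overlap_protein=overlap_prot,
        )
    raise SequenceError(
        f"no phasing pad yields a clean junction: {last_error}"
    )


def _pad_makes_motif(construct: str, L: int, k: int, spec: MotifSpec) -> bool:
    lo = max(0, L - spec.window_nt - 3)
    hi = min(len(construct), L + k + spec.window_nt)
    for sd_start, spacer, start_pos in match_motif(construct[lo:hi], spec):
        span = set(range(lo + sd_start, lo + sd_start + len(spec.sd_consensus)))
        span |= set(range(lo + start_pos, lo + start_pos + 3))
        if span & set(range(L, L + k)):
            return True
    return False
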