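"""Off-target site enumeration under positional-mask matching rules.

A :class:`RuleSet` captures one nuclease/effector's matching rule: spacer
length, PAM pattern and side, the tolerated-position mask, and a cap on
effective mismatches.  Two stock rules are provided:

* type I-F Cascade — 32-nt spacer, 5'-CC PAM, tolerated positions
  {6,12,18} ∪ {24..32}, ≤4 effective mismatches;
* SpCas9 comparator — 20-nt spacer, 3'-NGG PAM, no tolerated positions,
  ≤4 mismatches anywhere.

Enumeration is an exhaustive genome scan with a PAM-anchored prefilter
(only PAM-passing windows are Hamming-checked); correctness is guaranteed
by equivalence with :func:`brute_force_oracle`, a deliberately independent
position-by-position rescan.  Candidate off-targets are then optionally
restricted to promoter regions (any protospacer base within ±2 kb of a
TSS by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

from intervaltree import IntervalTree

from .guide_design import DesignWindows, DEFAULT_WINDOWS, extract_candidates
from .mismatch_model import PositionMask, effective_mismatches
from .sequence_io import (
    GenomeSequences,
    PromoterInterval,
    TssRecord,
    build_promoters,
    revcomp,
)

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class RuleSet:
    """An off-target matching specification for one effector."""

    name: str
    spacer_len: int
    pam_pattern: str
    pam_side: str  # '5prime' or '3prime', relative to the protospacer
    mask: PositionMask
    max_mismatches: int = 4
    require_pam_on_offtargets: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not self.pam_pattern or not set(self.pam_pattern) <= set(IUPAC):
            raise ValueError(f"pam_pattern {self.pam_pattern!r} is not a non-empty IUPAC string")
        if self.pam_side not in {"5prime", "3prime"}:
            raise ValueError("pam_side must be '5prime' or '3prime'")
        if self.mask.spacer_len != self.spacer_len:
            raise ValueError("mask.spacer_len inconsistent with rule spacer_len")


def cascade_rule(spacer_len: int = 32, max_mismatches: int = 4, mask: PositionMask | None = None) -> RuleSet:
    """Type I-F Cascade rule: 5'-CC PAM, masked {6,12,18,24..L}, ≤4 effective."""
    return RuleSet(
        name="cascade_if",
        spacer_len=spacer_len,
        pam_pattern="CC",
        pam_side="5prime",
        mask=mask or PositionMask.cascade_default(spacer_len),
        max_mismatches=max_mismatches,
    )


def spcas9_rule(max_mismatches: int = 4) -> RuleSet:
    """SpCas9 comparator rule: 20-nt spacer, 3'-NGG PAM, every mismatch counts."""
    return RuleSet(
        name="spcas9",
        spacer_len=20,
        pam_pattern="NGG",
        pam_side="3prime",
        mask=PositionMask.unmasked(20),
        max_mismatches=max_mismatches,
    )


@dataclass(frozen=True)
class OffTargetHit:
    """A genomic match to a query spacer under some rule set.

    ``site_seq`` is the protospacer-strand sequence 5'→3';
    ``mismatch_positions`` are 1-based PAM-proximal; ``pam_proximal_pos``
    is the forward-axis coordinate of the PAM-proximal protospacer base.
    ``tss_distance`` (set by :func:`promoter_filter`) is the forward-axis
    signed offset of that base from the nearest overlapped TSS.
    """

    seq_name: str
    strand: str
    protospacer_start: int
    site_seq: str
    pam_observed: str
    mismatch_positions: tuple[int, ...]
    effective_count: int
    is_on_target: bool
    pam_proximal_pos: int
    nearest_gene: str | None = None
    tss_distance: int | None = None

    @property
    def protospacer_end(self) -> int:
        return self.protospacer_start + len(self.site_seq)


def _pam_ok(observed: str, pattern: str) -> bool:
    # N in the genome never matches a PAM base, even against pattern N.
    return len(observed) == len(pattern) and all(
        b in IUPAC[p] for b, p in zip(observed, pattern)
    )


def _query_pp(query: str, pam_side: str) -> str:
    """Query spacer re-indexed PAM-proximal-first."""
    return query if pam_side == "5prime" else query[::-1]


def _validate_query(query: str, rule: RuleSet) -> None:
    if len(query) != rule.spacer_len:
        raise ValueError(f"query length {len(query)} != rule spacer_len {rule.spacer_len}")
    if not set(query) <= set("ACGT"):
        raise ValueError("query spacer must be unambiguous A/C/G/T")


def enumerate_offtargets(query_spacer: str, genome: GenomeSequences, rule: RuleSet) -> list[OffTargetHit]:
    """All genomic windows matching ``query_spacer`` under ``rule``.

    Every window on either strand with a rule-conformant PAM (when
    required) and ≤ ``rule.max_mismatches`` effective mismatches is
    returned exactly once, on forward-axis coordinates; exact matches are
    flagged on-target.
    """
    _validate_query(query_spacer, rule)
    if len(genome) == 0:
        raise ValueError("empty genome")
    L, P = rule.spacer_len, len(rule.pam_pattern)
    q_pp = _query_pp(query_spacer, rule.pam_side)
    hits: list[OffTargetHit] = []
    for name, fwd in genome.items():
        n = len(fwd)
        for strand, s in (("+", fwd), ("-", revcomp(fwd))):
            if rule.pam_side == "5prime":
                lo, hi = P, n - L
            else:
                lo, hi = 0, n - L - P
            for j in range(lo, hi + 1):
                if rule.pam_side == "5prime":
                    pam_obs = s[j - P:j]
                else:
                    pam_obs = s[j + L:j + L + P]
                if rule.require_pam_on_offtargets and not _pam_ok(pam_obs, rule.pam_pattern):
                    continue
                site = s[j:j + L]
                site_pp = site if rule.pam_side == "5prime" else site[::-1]
                eff, positions = effective_mismatches(q_pp, site_pp, rule.mask)
                if eff > rule.max_mismatches:
                    continue
                start = j if strand == "+" else n - j - L
                if rule.pam_side == "5prime":
                    anchor = start if strand == "+" else start + L - 1
                else:
                    anchor = start + L - 1 if strand == "+" else start
                hits.append(
                    OffTargetHit(
                        seq_name=name,
                        strand=strand,
                        protospacer_start=start,
                        site_seq=site,
                        pam_observed=pam_obs,
                        mismatch_positions=tuple(positions),
                        effective_count=eff,
                        is_on_target=not positions,
                        pam_proximal_pos=anchor,
                    )
                )
    hits.sort(key=lambda h: (h.seq_name, h.protospacer_start, h.strand))
    return hits


# --- independent verification oracle ------------------------------------

_ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


def brute_force_oracle(query_spacer: str, genome: GenomeSequences, rule: RuleSet) -> list[OffTargetHit]:
    """Exhaustive reference scan with no index or prefilter.

    Same contract as :func:`enumerate_offtargets`, implemented
    independently: every window on both strands is extracted directly on
    forward-axis coordinates and fully evaluated (PAM and all positions)
    before filtering.  Used to verify the production enumerator.
    """
    from Bio.Seq import Seq

    _validate_query(query_spacer, rule)
    if len(genome) == 0:
        raise ValueError("empty genome")
    L, P = rule.spacer_len, len(rule.pam_pattern)
    masked = rule.mask.masked
    hits = []
    for name, fwd in genome.items():
        n = len(fwd)
        for start in range(0, n - L + 1):
            window = fwd[start:start + L]
            for strand in ("+", "-"):
                if strand == "+":
                    site = window
                    if rule.pam_side == "5prime":
                        pam_fwd = fwd[max(0, start - P):start]
                        pam_obs = pam_fwd if start - P >= 0 else None
                    else:
                        pam_obs = fwd[start + L:start + L + P] if start + L + P <= n else None
                    anchor_pp = start if rule.pam_side == "5prime" else start + L - 1
                else:
                    site = str(Seq(window).reverse_complement())
                    if rule.pam_side == "5prime":
                        pam_obs = (
                            str(Seq(fwd[start + L:start + L + P]).reverse_complement())
                            if start + L + P <= n else None
                        )
                    else:
                        pam_obs = (
                            str(Seq(fwd[start - P:start]).reverse_complement())
                            if start - P >= 0 else None
                        )
                    anchor_pp = start + L - 1 if rule.pam_side == "5prime" else start
                if pam_obs is None:
                    continue
                pam_pass = all(
                    b in _ORACLE_IUPAC[p] and b != "N"
                    for b, p in zip(pam_obs, rule.pam_pattern)
                )
                if rule.require_pam_on_offtargets and not pam_pass:
                    continue
                positions = []
                for k in range(L):
                    # site and query are both 5'->3'; PAM-proximal index flips for 3' PAMs
                    pp = k + 1 if rule.pam_side == "5prime" else L - k
                    if site[k] != query_spacer[k] or site[k] == "N":
                        positions.append(pp)
                positions.sort()
                eff = sum(1 for p in positions if p not in masked)
                if eff > rule.max_mismatches:
                    continue
                hits.append(
                    OffTargetHit(
                        seq_name=name,
                        strand=strand,
                        protospacer_start=start,
                        site_seq=site,
                        pam_observed=pam_obs,
                        mismatch_positions=tuple(positions),
                        effective_count=eff,
                        is_on_target=not positions,
                        pam_proximal_pos=anchor_pp,
                    )
                )
    hits.sort(key=lambda h: (h.seq_name, h.protospacer_start, h.strand))
    return hits


def promoter_filter(hits: list[OffTargetHit], promoters: list[PromoterInterval]) -> list[OffTargetHit]:
    """Keep hits whose protospacer overlaps ≥1 promoter interval.

    Retained hits are annotated with the nearest overlapped gene (by
    |TSS - PAM-proximal base|, ties to the lexicographically smaller
    gene_id) and the signed forward-axis distance from that TSS.
    """
    trees: dict[str, IntervalTree] = {}
    for p in promoters:
        trees.setdefault(p.seq_name, IntervalTree()).addi(p.start, p.end, p)
    out = []
    for hit in hits:
        tree = trees.get(hit.seq_name)
        if tree is None:
            continue
        overlapping = [iv.data for iv in tree.overlap(hit.protospacer_start, hit.protospacer_end)]
        if not overlapping:
            continue
        nearest = min(overlapping, key=lambda p: (abs(p.tss - hit.pam_proximal_pos), p.gene_id))
        out.append(
            replace(hit, nearest_gene=nearest.gene_id, tss_distance=hit.pam_proximal_pos - nearest.tss)
        )
    return out


@dataclass(frozen=True)
class OverlapRegion:
    """A locus where a Cascade and a Cas9 protospacer overlap, each with
    predicted off-targets in another gene's promoter."""

    seq_name: str
    gene_id: str
    start: int
    end: int
    cascade_hit: OffTargetHit
    cas9_hit: OffTargetHit
    cascade_offtargets: tuple[OffTargetHit, ...]
    cas9_offtargets: tuple[OffTargetHit, ...]


def _iter_pam_windows(seq: str, rule: RuleSet):
    """Yield (strand, start) of every PAM-conformant window on forward coords."""
    n, L, P = len(seq), rule.spacer_len, len(rule.pam_pattern)
    rc = revcomp(seq)
    for strand, s in (("+", seq), ("-", rc)):
        if rule.pam_side == "5prime":
            rng = range(P, n - L + 1)
        else:
            rng = range(0, n - L - P + 1)
        for j in rng:
            pam_obs = s[j - P:j] if rule.pam_side == "5prime" else s[j + L:j + L + P]
            if _pam_ok(pam_obs, rule.pam_pattern):
                yield strand, (j if strand == "+" else n - j - L)


def find_overlap_sites(
    genome: GenomeSequences,
    tss_records: list[TssRecord],
    cascade: RuleSet,
    cas9: RuleSet,
    windows: DesignWindows = DEFAULT_WINDOWS,
    promoter_half_width: int = 2000,
) -> list[OverlapRegion]:
    """Loci targetable by both effectors, each with cross-promoter off-targets.

    For every Cascade guide candidate in a gene's design window, every
    Cas9 protospacer overlapping it by ≥1 bp is considered.  The pair is
    reported when both query spacers have ≥1 predicted off-target (their
    respective rules) surviving the promoter filter in a *different*
    gene's promoter.
    """
    regions: list[OverlapRegion] = []
    candidates = extract_candidates(genome, tss_records, cascade.spacer_len, windows, pam=cascade.pam_pattern)
    promoters = build_promoters(tss_records, promoter_half_width, genome)
    cascade_ot_cache: dict[str, list[OffTargetHit]] = {}
    cas9_ot_cache: dict[str, list[OffTargetHit]] = {}
    for cand in candidates:
        seq = genome[cand.seq_name]
        lo = max(0, cand.protospacer_start - cas9.spacer_len - len(cas9.pam_pattern))
        hi = min(len(seq), cand.protospacer_end + cas9.spacer_len + len(cas9.pam_pattern))
        sub = seq[lo:hi]
        other_promoters = [p for p in promoters if p.gene_id != cand.gene_id]

        if cand.spacer not in cascade_ot_cache:
            cascade_ot_cache[cand.spacer] = enumerate_offtargets(cand.spacer, genome, cascade)
        cascade_ots = tuple(
            h for h in promoter_filter(cascade_ot_cache[cand.spacer], other_promoters)
            if not (h.seq_name == cand.seq_name and h.protospacer_start == cand.protospacer_start)
        )
        if not cascade_ots:
            continue

        for strand, local_start in _iter_pam_windows(sub, cas9):
            start = lo + local_start
            end = start + cas9.spacer_len
            if min(end, cand.protospacer_end) - max(start, cand.protospacer_start) < 1:
                continue
            window = seq[start:end]
            if "N" in window:
                continue
            cas9_spacer = window if strand == "+" else revcomp(window)
            if cas9_spacer not in cas9_ot_cache:
                cas9_ot_cache[cas9_spacer] = enumerate_offtargets(cas9_spacer, genome, cas9)
            cas9_all = cas9_ot_cache[cas9_spacer]
            cas9_ots = tuple(
                h for h in promoter_filter(cas9_all, other_promoters)
                if not (h.seq_name == cand.seq_name and h.protospacer_start == start)
            )
            if not cas9_ots:
                continue
            cas9_on = next(
                h for h in cas9_all
                if h.seq_name == cand.seq_name and h.protospacer_start == start and h.strand == strand
            )
            cascade_on = next(
                h for h in cascade_ot_cache[cand.spacer]
                if h.seq_name == cand.seq_name and h.protospacer_start == cand.protospacer_start
                and h.strand == cand.strand
            )
            regions.append(
                OverlapRegion(
                    seq_name=cand.seq_name,
                    gene_id=cand.gene_id,
                    start=min(cand.protospacer_start, start),
                    end=max(cand.protospacer_end, end),
                    cascade_hit=cascade_on,
                    cas9_hit=cas9_on,
                    cascade_offtargets=cascade_ots,
                    cas9_offtargets=cas9_ots,
                )
            )
    regions.sort(key=lambda r: (r.seq_name, r.start, r.end, r.gene_id))
    return regions


def render_site(hit: OffTargetHit, pam_side: str = "5prime") -> str:
    """Protospacer-strand site with mismatched bases rendered lowercase."""
    L = len(hit.site_seq)
    chars = list(hit.site_seq)
    for p in hit.mismatch_positions:
        idx = p - 1 if pam_side == "5prime" else L - p
        chars[idx] = chars[idx].lower()
    return "".join(chars)


def report(
    hits: list[OffTargetHit],
    path: str | Path,
    fmt: str = "tsv",
    pam_side: str = "5prime",
    label: str = "hit",
) -> None:
    """Write hits as TSV (with header) or BED6, deterministically ordered.

    BED rows use the 0-based half-open protospacer interval; the score
    column carries the effective mismatch count.  TSV ``site_seq`` renders
    mismatched bases in lowercase.
    """
    ordered = sorted(hits, key=lambda h: (h.seq_name, h.protospacer_start, h.strand))
    path = Path(path)
    if fmt == "tsv":
        import pandas as pd

        rows = [
            {
                "seq_name": h.seq_name,
                "strand": h.strand,
                "start": h.protospacer_start,
                "end": h.protospacer_end,
                "site_seq": render_site(h, pam_side),
                "pam": h.pam_observed,
                "mismatch_positions": ",".join(map(str, h.mismatch_positions)),
                "effective_mismatches": h.effective_count,
                "on_target": h.is_on_target,
                "nearest_gene": h.nearest_gene if h.nearest_gene is not None else "",
                "tss_distance": h.tss_distance if h.tss_distance is not None else "",
            }
            for h in ordered
        ]
        pd.DataFrame(
            rows,
            columns=[
                "seq_name", "strand", "start", "end", "site_seq", "pam",
                "mismatch_positions", "effective_mismatches", "on_target",
                "nearest_gene", "tss_distance",
            ],
        ).to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        with open(path, "w") as fh:
            for i, h in enumerate(ordered):
                fh.write(
                    f"{h.seq_name}\t{h.protospacer_start}\t{h.protospacer_end}\t"
                    f"{label}_{i}\t{h.effective_count}\t{h.strand}\n"
                )
    else:
        raise ValueError(f"unknown report format {fmt!r}")
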