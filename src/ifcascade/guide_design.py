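"""Guide (crRNA spacer) design for type I-F Cascade CRISPRa.

The type I-F Cascade recognizes a 5'-CC PAM on the non-target strand; the
crRNA spacer is taken identical in sequence to the protospacer on the
strand carrying that PAM.  Guides are designed against a window upstream of
a gene's TSS: the design range defaults to [-500, -100] bp and the optimal
window to [-200, -100] bp, both measured gene-strand-relative from the
PAM-proximal protospacer base (negative = upstream).

Csy3 stoichiometry follows the 6 nt-per-subunit rule: a spacer of length L
recruits ceil(L/6) Csy3 copies (6 for the canonical 32-nt spacer; 3 at the
14-nt minimum and 9 at 50 nt).  Spacers may be extended at the PAM-distal
end in steps of 6 nt (32, 38, 44, 50, 56, ...) to recruit more activator-
fused Csy3 copies.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace

from .sequence_io import GenomeSequences, TssRecord, revcomp

logger = logging.getLogger(__name__)

WINDOW_ORDER = {"optimal": 0, "in_range": 1, "out_of_range": 2}

#: Spacer lengths with demonstrated activity; longer multiples of six are
#: accepted but flagged with a warning.
MAX_VALIDATED_SPACER_LEN = 56


@dataclass(frozen=True)
class DesignWindows:
    """TSS-offset windows (gene-strand-relative, negative = upstream)."""

    design_range: tuple[int, int] = (-500, -100)
    optimal_window: tuple[int, int] = (-200, -100)

    def __post_init__(self) -> None:
        for lo, hi in (self.design_range, self.optimal_window):
            if lo > hi:
                raise ValueError(f"window ({lo}, {hi}) has lo > hi")

    @property
    def optimal_center(self) -> float:
        lo, hi = self.optimal_window
        return (lo + hi) / 2


DEFAULT_WINDOWS = DesignWindows()


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer + 5'-CC PAM hit annotated for one gene.

    ``strand`` is the strand whose sequence equals the spacer; coordinates
    are 0-based half-open on the forward axis.  ``tss_offset`` is measured
    from the PAM-proximal protospacer base to the TSS, gene-strand-relative
    (negative = upstream).
    """

    gene_id: str
    seq_name: str
    strand: str
    protospacer_start: int
    protospacer_end: int
    pam: str
    spacer: str
    tss_offset: int
    window_class: str
    csy3_copies: int

    @property
    def pam_proximal_pos(self) -> int:
        """Forward-axis coordinate of the PAM-proximal protospacer base."""
        return self.protospacer_start if self.strand == "+" else self.protospacer_end - 1


@dataclass(frozen=True)
class GuidePair:
    """Two guides for one gene, with their genomic spacing.

    Spacing is measured between the two protospacers' leftmost (5'-most on
    the forward axis) positions; 50-75 bp spacing is classed optimal.
    """

    first: GuideCandidate
    second: GuideCandidate
    spacing: int
    spacing_class: str


def scan_pam_sites(seq: str, spacer_len: int, pam: str = "CC") -> list[tuple[str, int]]:
    """Find all protospacers with a 5' PAM on either strand.

    Returns ``(strand, protospacer_start)`` tuples with forward-axis
    coordinates for both strands, sorted by position.  Windows containing N
    are excluded, and N never matches a PAM base.
    """
    if spacer_len < 1:
        raise ValueError(f"spacer_len must be >= 1, got {spacer_len}")
    if not seq:
        raise ValueError("empty sequence")
    n, L, P = len(seq), spacer_len, len(pam)
    rc_pam = revcomp(pam)
    hits: list[tuple[str, int]] = []
    for i in range(P, n - L + 1):
        if seq[i - P:i] == pam and "N" not in seq[i:i + L]:
            hits.append(("+", i))
    for i in range(0, n - L - P + 1):
        if seq[i + L:i + L + P] == rc_pam and "N" not in seq[i:i + L]:
            hits.append(("-", i))
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits


def classify_tss_window(tss_offset: int, windows: DesignWindows = DEFAULT_WINDOWS) -> str:
    """Classify a gene-strand-relative TSS offset.

    ``optimal`` within the optimal window (inclusive); ``in_range`` within
    the design range; ``out_of_range`` otherwise.
    """
    olo, ohi = windows.optimal_window
    dlo, dhi = windows.design_range
    if olo <= tss_offset <= ohi:
        return "optimal"
    if dlo <= tss_offset <= dhi:
        return "in_range"
    return "out_of_range"


def csy3_copies(spacer_len: int) -> int:
    """Number of Csy3 subunits recruited by a spacer: ceil(L / 6).

    Each Csy3 binds 6 nt of spacer; 6 nt is the minimal binding unit, so
    lengths below 6 are rejected.
    """
    if spacer_len < 6:
        raise ValueError(f"spacer_len {spacer_len} below the 6-nt minimal Csy3 binding unit")
    return math.ceil(spacer_len / 6)


def _tss_offset(strand: str, start: int, end: int, gene: TssRecord) -> int:
    anchor = start if strand == "+" else end - 1
    return anchor - gene.tss if gene.strand == "+" else gene.tss - anchor


def extract_candidates(
    genome: GenomeSequences,
    tss_records: list[TssRecord],
    spacer_len: int = 32,
    windows: DesignWindows = DEFAULT_WINDOWS,
    pam: str = "CC",
) -> list[GuideCandidate]:
    """Find all PAM-adjacent protospacers within each gene's design range.

    Both strands are scanned; a site is assigned to a gene when its
    PAM-proximal base lies inside the design range relative to that gene's
    TSS.  Candidates carry window class and Csy3 copy number.
    """
    if not tss_records:
        raise ValueError("no TSS records supplied")
    dlo, dhi = windows.design_range
    reach = max(abs(dlo), abs(dhi)) + spacer_len + len(pam) + 2
    out: list[GuideCandidate] = []
    for gene in tss_records:
        if gene.seq_name not in genome:
            raise KeyError(f"gene {gene.gene_id!r} is on unknown sequence {gene.seq_name!r}")
        seq = genome[gene.seq_name]
        lo = max(0, gene.tss - reach)
        hi = min(len(seq), gene.tss + reach)
        for strand, local_start in scan_pam_sites(seq[lo:hi], spacer_len, pam):
            start = lo + local_start
            end = start + spacer_len
            off = _tss_offset(strand, start, end, gene)
            if not (dlo <= off <= dhi):
                continue
            spacer = seq[start:end] if strand == "+" else revcomp(seq[start:end])
            pam_obs = seq[start - len(pam):start] if strand == "+" else revcomp(seq[end:end + len(pam)])
            out.append(
                GuideCandidate(
                    gene_id=gene.gene_id,
                    seq_name=gene.seq_name,
                    strand=strand,
                    protospacer_start=start,
                    protospacer_end=end,
                    pam=pam_obs,
                    spacer=spacer,
                    tss_offset=off,
                    window_class=classify_tss_window(off, windows),
                    csy3_copies=csy3_copies(spacer_len),
                )
            )
    return out


def _check_extension_len(target_len: int) -> None:
    if target_len < 32 or (target_len - 32) % 6 != 0:
        raise ValueError(f"target_len must be 32 + 6k (32, 38, 44, ...), got {target_len}")
    if target_len > MAX_VALIDATED_SPACER_LEN:
        logger.warning("spacer length %d exceeds the validated maximum of %d nt", target_len, MAX_VALIDATED_SPACER_LEN)


def extend_spacer(candidate: GuideCandidate, target_len: int, genome: GenomeSequences) -> GuideCandidate:
    """Extend a spacer at the PAM-distal end with its genomic continuation.

    The PAM-proximal 32 nt are unchanged; ``target_len`` must be of the
    form 32 + 6k.  Extension beyond the sequence end is an error.
    """
    _check_extension_len(target_len)
    L = len(candidate.spacer)
    if target_len < L:
        raise ValueError(f"target_len {target_len} shorter than current spacer ({L} nt); use truncate_spacer")
    if target_len == L:
        return candidate
    seq = genome[candidate.seq_name]
    delta = target_len - L
    if candidate.strand == "+":
        new_start, new_end = candidate.protospacer_start, candidate.protospacer_end + delta
        if new_end > len(seq):
            raise ValueError("extension exceeds sequence bounds")
        spacer = seq[new_start:new_end]
    else:
        new_start, new_end = candidate.protospacer_start - delta, candidate.protospacer_end
        if new_start < 0:
            raise ValueError("extension exceeds sequence bounds")
        spacer = revcomp(seq[new_start:new_end])
    return replace(
        candidate,
        protospacer_start=new_start,
        protospacer_end=new_end,
        spacer=spacer,
        csy3_copies=csy3_copies(target_len),
    )


def truncate_spacer(candidate: GuideCandidate, target_len: int) -> GuideCandidate:
    """Trim a spacer back to ``target_len`` (32 + 6k), keeping the PAM-proximal end."""
    _check_extension_len(target_len)
    L = len(candidate.spacer)
    if target_len > L:
        raise ValueError(f"target_len {target_len} longer than current spacer ({L} nt); use extend_spacer")
    delta = L - target_len
    if candidate.strand == "+":
        new_start, new_end = candidate.protospacer_start, candidate.protospacer_end - delta
    else:
        new_start, new_end = candidate.protospacer_start + delta, candidate.protospacer_end
    return replace(
        candidate,
        protospacer_start=new_start,
        protospacer_end=new_end,
        spacer=candidate.spacer[:target_len],
        csy3_copies=csy3_copies(target_len),
    )


def select_pairs(
    candidates: list[GuideCandidate],
    spacing_window: tuple[int, int] = (50, 75),
) -> list[GuidePair]:
    """Enumerate all guide pairs for one gene, optimal spacing first.

    Spacing between the two protospacers' leftmost genomic positions of
    50-75 bp is classed ``optimal``, anything else ``acceptable``.  Pairs
    are sorted optimal-first, then by distance from the window midpoint.
    Fewer than two candidates yields an empty list.
    """
    if len(candidates) < 2:
        return []
    gene_ids = {c.gene_id for c in candidates}
    if len(gene_ids) != 1:
        raise ValueError(f"pair selection requires candidates for a single gene, got {sorted(gene_ids)}")
    lo, hi = spacing_window
    mid = (lo + hi) / 2
    pairs = []
    for a, b in itertools.combinations(candidates, 2):
        if b.protospacer_start < a.protospacer_start:
            a, b = b, a
        spacing = b.protospacer_start - a.protospacer_start
        cls = "optimal" if lo <= spacing <= hi else "acceptable"
        pairs.append(GuidePair(a, b, spacing, cls))
    pairs.sort(
        key=lambda p: (
            0 if p.spacing_class == "optimal" else 1,
            abs(p.spacing - mid),
            p.first.protospacer_start,
            p.second.protospacer_start,
        )
    )
    return pairs


def rank_candidates(
    candidates: list[GuideCandidate],
    windows: DesignWindows = DEFAULT_WINDOWS,
) -> list[GuideCandidate]:
    """Stable sort: optimal window first, then proximity to the window center.

    Ties are broken by forward coordinate, then input order (stable sort).
    """
    center = windows.optimal_center
    return sorted(
        candidates,
        key=lambda c: (
            WINDOW_ORDER[c.window_class],
            abs(c.tss_offset - center),
            c.protospacer_start,
        ),
    )
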