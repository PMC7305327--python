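"""Positional mismatch tolerance of type I-F crRNA:DNA pairing.

Cascade binding tolerates mismatches unevenly along the 32-nt spacer.
Every sixth base of the crRNA is flipped out of the RNA:DNA duplex (the
5+1 pairing pattern), so mismatches at positions 6, 12, 18 and 24 have
little effect; PAM-distal positions 24-32 are likewise tolerant, while the
PAM-proximal seed (positions 1-5, 7, 8) is critical for target engagement.
The off-target search therefore counts only *effective* mismatches — those
outside the tolerated (masked) positions {6, 12, 18} ∪ {24..32}.

Conventions: spacer positions are 1-based counting from the PAM-proximal
end, and all paired strings handed to :func:`effective_mismatches` are
indexed the same way (position 1 = index 0).
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PositionMask:
    """Tolerated (masked) and seed positions of a spacer, 1-based PAM-proximal."""

    spacer_len: int
    masked: frozenset[int]
    seed: frozenset[int]

    def __post_init__(self) -> None:
        if self.spacer_len < 1:
            raise ValueError("spacer_len must be positive")
        valid = set(range(1, self.spacer_len + 1))
        if not set(self.masked) <= valid:
            raise ValueError(f"masked positions outside [1, {self.spacer_len}]")
        if not set(self.seed) <= valid:
            raise ValueError(f"seed positions outside [1, {self.spacer_len}]")

    @classmethod
    def cascade_default(cls, spacer_len: int = 32) -> "PositionMask":
        """Tolerated positions {6,12,18} ∪ {24..L}; seed {1..8} minus 6."""
        masked = {p for p in (6, 12, 18) if p <= spacer_len}
        masked |= set(range(24, spacer_len + 1))
        seed = {p for p in (1, 2, 3, 4, 5, 7, 8) if p <= spacer_len}
        return cls(spacer_len=spacer_len, masked=frozenset(masked), seed=frozenset(seed))

    @classmethod
    def unmasked(cls, spacer_len: int) -> "PositionMask":
        """No tolerated positions: every mismatch counts (SpCas9-style rule)."""
        return cls(spacer_len=spacer_len, masked=frozenset(), seed=frozenset())


@dataclass(frozen=True)
class MismatchVariant:
    """A spacer variant differing from its reference at listed positions."""

    positions: tuple[int, ...]
    variant_spacer: str
    label: str


def complement_base(base: str) -> str:
    """Watson-Crick complement of a single unambiguous base."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"cannot complement base {base!r}") from None


def effective_mismatches(
    spacer: str, site_seq: str, mask: PositionMask
) -> tuple[int, list[int]]:
    """Count mismatches outside the tolerated positions.

    Both strings must be ``mask.spacer_len`` long and aligned PAM-proximal
    first.  An N in the genomic site always counts as a mismatch.  Returns
    ``(effective_count, all_mismatch_positions)`` with positions 1-based.
    """
    if len(spacer) != mask.spacer_len or len(site_seq) != mask.spacer_len:
        raise ValueError(
            f"length mismatch: spacer {len(spacer)}, site {len(site_seq)}, mask {mask.spacer_len}"
        )
    positions = [
        i + 1 for i, (a, b) in enumerate(zip(spacer, site_seq)) if a != b or b == "N"
    ]
    effective = sum(1 for p in positions if p not in mask.masked)
    return effective, positions


def apply_mismatches(spacer: str, positions: list[int] | tuple[int, ...]) -> str:
    """Substitute the complement base at each 1-based position of ``spacer``."""
    out = list(spacer)
    for p in positions:
        if not 1 <= p <= len(spacer):
            raise ValueError(f"position {p} outside [1, {len(spacer)}]")
        out[p - 1] = complement_base(spacer[p - 1])
    return "".join(out)


def single_mismatch_panel(spacer: str) -> list[MismatchVariant]:
    """One variant per spacer position, substituting the complement base.

    For the canonical 32-nt spacer this yields the 32-variant
    single-mismatch panel; the construction generalizes to any length L
    (L variants).
    """
    if not spacer:
        raise ValueError("empty spacer")
    return [
        MismatchVariant(
            positions=(p,),
            variant_spacer=apply_mismatches(spacer, [p]),
            label=f"mm{p:02d}",
        )
        for p in range(1, len(spacer) + 1)
    ]


def block_mismatch_panel(spacer: str, block_len: int = 6) -> list[MismatchVariant]:
    """Non-overlapping fully-complemented blocks starting at position 1.

    A 32-nt spacer with 6-nt blocks yields five variants covering
    positions 1-30 (the trailing 2 nt are left uncovered).
    """
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    if len(spacer) < block_len:
        raise ValueError(f"spacer ({len(spacer)} nt) shorter than block_len {block_len}")
    variants = []
    for k in range(len(spacer) // block_len):
        positions = tuple(range(k * block_len + 1, (k + 1) * block_len + 1))
        variants.append(
            MismatchVariant(
                positions=positions,
                variant_spacer=apply_mismatches(spacer, positions),
                label=f"block{positions[0]:02d}-{positions[-1]:02d}",
            )
        )
    return variants


def classify_position(pos: int, spacer_len: int = 32) -> str:
    """Functional class of a spacer position (1-based, PAM-proximal).

    ``seed`` for 1-5, 7, 8; ``periodic_tolerant`` for the flipped-out every-
    sixth positions 6, 12, 18, 24; ``distal_tolerant`` for 25..L;
    ``internal`` otherwise.
    """
    if not 1 <= pos <= spacer_len:
        raise ValueError(f"position {pos} outside [1, {spacer_len}]")
    if pos in {1, 2, 3, 4, 5, 7, 8}:
        return "seed"
    if pos % 6 == 0 and pos <= 24:
        return "periodic_tolerant"
    if pos >= 25:
        return "distal_tolerant"
    return "internal"
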