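"""CRISPR array assembly and in-silico Csy4 processing.

A type I-F CRISPR array is transcribed as one pre-crRNA laid out
``DR-spacer1-DR-spacer2-...-DR`` (n spacers bounded by n+1 direct repeats).
Csy4 cleaves within each 28-nt direct repeat after position 20 (1-based),
so each mature crRNA consists of the last 8 nt of one repeat (the 5'
handle bound by Csy1/Csy2), the spacer, and the first 20 nt of the next
repeat (the 3' hairpin bound by Csy4).  The 20-nt leader of the first
repeat and the 8-nt trailer of the last repeat are released as terminal
by-products, not crRNAs.

The repeat nucleotide sequence is a required configuration value: no
default repeat is assumed for design work (the test-suite uses a clearly
labelled example repeat from :mod:`ifcascade.synthetic_data`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequence_io import NUCLEOTIDES, SequenceError


@dataclass(frozen=True)
class RepeatSpec:
    """A direct repeat (DR) split into its hairpin and handle segments.

    The canonical type I-F repeat is 28 nt: cleavage after position 20
    leaves a 20-nt hairpin upstream of the cut and an 8-nt handle
    downstream — the register forced by the 8-nt handle + 20-nt hairpin
    architecture of the mature crRNA.
    """

    repeat_seq: str
    handle_len: int = 8
    hairpin_len: int = 20

    def __post_init__(self) -> None:
        if not set(self.repeat_seq) <= NUCLEOTIDES - {"N"}:
            raise SequenceError("repeat sequence must be unambiguous A/C/G/T")
        if self.handle_len <= 0 or self.hairpin_len <= 0:
            raise ValueError("handle_len and hairpin_len must be positive")
        if len(self.repeat_seq) != self.handle_len + self.hairpin_len:
            raise ValueError(
                f"repeat length {len(self.repeat_seq)} != handle_len + hairpin_len "
                f"= {self.handle_len + self.hairpin_len}"
            )

    @property
    def hairpin(self) -> str:
        """First ``hairpin_len`` nt of the repeat (upstream of the Csy4 cut)."""
        return self.repeat_seq[: self.hairpin_len]

    @property
    def handle(self) -> str:
        """Last ``handle_len`` nt of the repeat (downstream of the Csy4 cut)."""
        return self.repeat_seq[self.hairpin_len :]


@dataclass(frozen=True)
class MatureCrRNA:
    """One processed crRNA: 5' handle + spacer + 3' hairpin."""

    handle: str
    spacer: str
    hairpin: str

    @property
    def sequence(self) -> str:
        return self.handle + self.spacer + self.hairpin

    def __len__(self) -> int:
        return len(self.handle) + len(self.spacer) + len(self.hairpin)


@dataclass(frozen=True)
class CrisprArray:
    """A multi-spacer CRISPR array and its pre-crRNA transcript."""

    spacers: tuple[str, ...]
    repeat: RepeatSpec
    pre_crrna: str = field(default="")

    def __post_init__(self) -> None:
        expected = self.repeat.repeat_seq + "".join(
            s + self.repeat.repeat_seq for s in self.spacers
        )
        if not self.pre_crrna:
            object.__setattr__(self, "pre_crrna", expected)
        elif self.pre_crrna != expected:
            raise ValueError("pre_crrna inconsistent with DR-spacer-...-DR layout")


def assemble_array(spacers: list[str], repeat: RepeatSpec) -> CrisprArray:
    """Build a pre-crRNA ``DR s1 DR s2 ... DR`` from ordered spacers."""
    if not spacers:
        raise ValueError("at least one spacer is required")
    for i, s in enumerate(spacers):
        if len(s) < 6:
            raise ValueError(f"spacer {i} is {len(s)} nt; minimum is the 6-nt Csy3 binding unit")
        if not set(s) <= NUCLEOTIDES - {"N"}:
            raise SequenceError(f"spacer {i} contains non-ACGT characters")
    return CrisprArray(spacers=tuple(spacers), repeat=repeat)


def process_array(array: CrisprArray) -> list[MatureCrRNA]:
    """Simulate Csy4 processing of a pre-crRNA into mature crRNAs.

    Each repeat is cut after its 20th nt, yielding one crRNA per spacer:
    ``handle(8) + spacer + hairpin(20)``, in array order.
    """
    rep = array.repeat
    crrnas = []
    pos = 0
    pre = array.pre_crrna
    for spacer in array.spacers:
        if pre[pos : pos + len(rep.repeat_seq)] != rep.repeat_seq:
            raise ValueError("malformed pre-crRNA: repeat expected at position %d" % pos)
        handle = pre[pos + rep.hairpin_len : pos + len(rep.repeat_seq)]
        pos += len(rep.repeat_seq)
        sp = pre[pos : pos + len(spacer)]
        pos += len(spacer)
        hairpin = pre[pos : pos + rep.hairpin_len]
        crrnas.append(MatureCrRNA(handle=handle, spacer=sp, hairpin=hairpin))
    if pre[pos:] != rep.repeat_seq:
        raise ValueError("malformed pre-crRNA: terminal repeat missing")
    return crrnas


def terminal_fragments(array: CrisprArray) -> tuple[str, str]:
    """By-products of processing: the 5' leader (20 nt) and 3' trailer (8 nt)."""
    rep = array.repeat
    return rep.hairpin, rep.handle


def validate_array(array: CrisprArray) -> list[str]:
    """Sanity warnings for an array design (never raises).

    Flags duplicate spacers, spacers embedding the full repeat (which would
    create spurious Csy4 processing sites), and spacer lengths outside the
    32 + 6k design set.
    """
    warnings = []
    seen: dict[str, int] = {}
    for i, s in enumerate(array.spacers):
        if s in seen:
            warnings.append(f"spacer {i} duplicates spacer {seen[s]}")
        else:
            seen[s] = i
        if array.repeat.repeat_seq in s:
            warnings.append(f"spacer {i} contains the direct repeat as a substring (spurious processing site)")
        if len(s) < 32 or (len(s) - 32) % 6 != 0:
            warnings.append(f"spacer {i} length {len(s)} is not of the form 32 + 6k")
    return warnings
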