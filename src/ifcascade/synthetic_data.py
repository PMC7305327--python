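"""Seeded synthetic genomes with planted guides, decoys and ground truth.

The study's inputs — a large annotated genome with promoters harbouring
CC-PAM protospacers and near-match decoy sites — are emulated here at desk
scale: i.i.d. background sequence at human-like GC content (0.41), genes
annotated only by a TSS and strand, on-target protospacers written at
controlled gene-strand-relative TSS offsets, and off-target decoys derived
from a reference spacer by complement substitutions at chosen PAM-proximal
positions.  Every plant is recorded in a :class:`TruthEntry` carrying its
expected fate under the default Cascade rule (detectable iff ≤4 effective
mismatches; promoter-retained iff the protospacer overlaps a ±2 kb TSS
window), so end-to-end tests can verify the pipeline against known truth.

A single integer seed drives all randomness.  Collisions between planted
features are resolved by bounded retry (100 attempts, deterministic given
the seed); the generator also rejects loci where the planted site would
duplicate an existing exact occurrence elsewhere in the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mismatch_model import apply_mismatches, effective_mismatches
from .offtarget_search import RuleSet, cascade_rule
from .sequence_io import (
    GenomeSequences,
    TssRecord,
    build_promoters,
    revcomp,
    write_tss_bed,
)

logger = logging.getLogger(__name__)

DEFAULT_GC = 0.41

#: 28-nt example direct repeat (synthetic stand-in used by tests and demos;
#: production array design requires the user's own repeat sequence).
EXAMPLE_REPEAT = "GTTCACTGCCGTATAGGCAGCTAAGAAA"

_BASES = np.array(list("ACGT"))


class PlantingError(RuntimeError):
    """A feature could not be placed (collision or duplicate site)."""


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one planted feature.

    ``tss_offset`` is gene-strand-relative from the PAM-proximal base
    (None for features planted at random loci); ``detectable`` means the
    effective mismatch count passes the rule cap; ``within_promoter``
    means the protospacer overlaps a promoter interval of the genes
    present at planting time.
    """

    kind: str  # 'on_target' or 'decoy'
    gene_id: str | None
    seq_name: str
    strand: str
    start: int
    end: int
    spacer_ref: str
    spacer_planted: str
    mismatch_positions: tuple[int, ...]
    tss_offset: int | None
    expected_effective: int
    detectable: bool
    within_promoter: bool | None


class SyntheticDataset:
    """A mutable synthetic genome plus annotations and planted truth."""

    def __init__(self, sequences: dict[str, str], seed: int):
        self._seqs: dict[str, bytearray] = {
            name: bytearray(seq.encode()) for name, seq in sequences.items()
        }
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.tss_records: list[TssRecord] = []
        self.truth: list[TruthEntry] = []
        self._occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in self._seqs}

    def genome(self) -> GenomeSequences:
        return GenomeSequences({name: s.decode() for name, s in self._seqs.items()})

    def seq_len(self, name: str) -> int:
        return len(self._seqs[name])

    # -- internal helpers --------------------------------------------------

    def _collides(self, seq_name: str, start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in self._occupied[seq_name])

    def _occupy(self, seq_name: str, start: int, end: int) -> None:
        self._occupied[seq_name].append((start, end))

    def _write(self, seq_name: str, pos: int, fragment: str) -> bytes:
        buf = self._seqs[seq_name]
        old = bytes(buf[pos:pos + len(fragment)])
        buf[pos:pos + len(fragment)] = fragment.encode()
        return old

    def _count_occurrences(self, fragment: str) -> int:
        total = 0
        targets = {fragment, revcomp(fragment)}
        for buf in self._seqs.values():
            text = buf.decode()
            for t in targets:
                i = text.find(t)
                while i != -1:
                    total += 1
                    i = text.find(t, i + 1)
        if fragment == revcomp(fragment):  # palindromes counted once per locus
            total //= 2
        return total


def generate_genome(
    n_seqs: int = 1,
    length: int = 50_000,
    gc: float = DEFAULT_GC,
    seed: int = 0,
) -> SyntheticDataset:
    """I.i.d. random genome with P(G) = P(C) = gc/2; reproducible by seed."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    rng = np.random.default_rng(seed)
    at = (1 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]
    seqs = {
        f"chr{i + 1}": "".join(rng.choice(_BASES, size=length, p=probs))
        for i in range(n_seqs)
    }
    return SyntheticDataset(seqs, seed)


def plant_gene(ds: SyntheticDataset, seq_name: str, tss: int, strand: str, gene_id: str) -> TssRecord:
    """Annotate a TSS; the surrounding sequence is left untouched."""
    if seq_name not in ds._seqs:
        raise KeyError(f"unknown sequence {seq_name!r}")
    if not 0 <= tss < ds.seq_len(seq_name):
        raise ValueError(f"TSS {tss} outside sequence {seq_name!r}")
    if any(rec.gene_id == gene_id for rec in ds.tss_records):
        raise ValueError(f"duplicate gene_id {gene_id!r}")
    rec = TssRecord(gene_id, seq_name, tss, strand)
    ds.tss_records.append(rec)
    return rec


def _site_geometry(strand: str, anchor: int, spacer_len: int, pam_len: int, pam_side: str):
    """Forward-axis (proto_start, proto_end, pam_start, pam_end) for an anchor.

    The anchor is the PAM-proximal protospacer base.
    """
    L, P = spacer_len, pam_len
    if pam_side == "5prime":
        if strand == "+":
            return anchor, anchor + L, anchor - P, anchor
        return anchor - L + 1, anchor + 1, anchor + 1, anchor + 1 + P
    if strand == "+":
        return anchor - L + 1, anchor + 1, anchor + 1, anchor + 1 + P
    return anchor, anchor + L, anchor - P, anchor


def _concrete_pam(pattern: str, rng: np.random.Generator) -> str:
    from .offtarget_search import IUPAC

    return "".join(
        c if c in "ACGT" else str(rng.choice(sorted(IUPAC[c]))) for c in pattern
    )


def _plant_site(
    ds: SyntheticDataset,
    spacer_variant: str,
    strand: str,
    seq_name: str,
    anchor: int,
    rule: RuleSet,
    pam_seq: str | None = None,
    ensure_unique: bool = True,
) -> tuple[int, int]:
    """Write PAM + protospacer at a PAM-proximal anchor; returns protospacer span.

    ``spacer_variant`` is given 5'→3' on the protospacer strand.  Raises
    :class:`PlantingError` on collision with previously planted features
    or (when ``ensure_unique``) if the written site already occurs
    elsewhere in the genome.
    """
    L, P = len(spacer_variant), len(rule.pam_pattern)
    pam = pam_seq or _concrete_pam(rule.pam_pattern, ds.rng)
    ps, pe, ms, me = _site_geometry(strand, anchor, L, P, rule.pam_side)
    lo, hi = min(ps, ms), max(pe, me)
    if lo < 0 or hi > ds.seq_len(seq_name):
        raise ValueError(f"site at anchor {anchor} exceeds bounds of {seq_name!r}")
    if ds._collides(seq_name, lo, hi):
        raise PlantingError(f"collision at {seq_name}:{lo}-{hi}")
    proto_fwd = spacer_variant if strand == "+" else revcomp(spacer_variant)
    pam_fwd = pam if strand == "+" else revcomp(pam)
    old_proto = ds._write(seq_name, ps, proto_fwd)
    old_pam = ds._write(seq_name, ms, pam_fwd)
    full_fwd = ds._seqs[seq_name][lo:hi].decode()
    if ensure_unique and ds._count_occurrences(full_fwd) > 1:
        # undo the write so a retry elsewhere starts from a clean genome
        ds._write(seq_name, ms, old_pam.decode())
        ds._write(seq_name, ps, old_proto.decode())
        raise PlantingError(f"planted site at {seq_name}:{lo} duplicates an existing locus")
    ds._occupy(seq_name, lo, hi)
    return ps, pe


def _gene_anchor(gene: TssRecord, tss_offset: int) -> int:
    """Forward-axis PAM-proximal anchor for a gene-strand-relative offset."""
    return gene.tss + tss_offset if gene.strand == "+" else gene.tss - tss_offset


def _lookup_gene(ds: SyntheticDataset, gene: TssRecord | str) -> TssRecord:
    if isinstance(gene, TssRecord):
        return gene
    for rec in ds.tss_records:
        if rec.gene_id == gene:
            return rec
    raise KeyError(f"unknown gene {gene!r}")


def plant_on_target(
    ds: SyntheticDataset,
    gene: TssRecord | str,
    spacer: str,
    tss_offset: int,
    rule: RuleSet | None = None,
) -> TruthEntry:
    """Write ``PAM + spacer`` in gene-strand orientation at a TSS offset.

    The offset is measured at the PAM-proximal base (negative = upstream).
    Overwrites background sequence; collisions with earlier plants raise.
    """
    rule = rule or cascade_rule(len(spacer))
    if not set(spacer) <= set("ACGT"):
        raise ValueError("spacer must be unambiguous A/C/G/T")
    gene = _lookup_gene(ds, gene)
    anchor = _gene_anchor(gene, tss_offset)
    start, end = _plant_site(ds, spacer, gene.strand, gene.seq_name, anchor, rule)
    entry = TruthEntry(
        kind="on_target",
        gene_id=gene.gene_id,
        seq_name=gene.seq_name,
        strand=gene.strand,
        start=start,
        end=end,
        spacer_ref=spacer,
        spacer_planted=spacer,
        mismatch_positions=(),
        tss_offset=tss_offset,
        expected_effective=0,
        detectable=True,
        within_promoter=None,
    )
    ds.truth.append(entry)
    return entry


def plant_decoy(
    ds: SyntheticDataset,
    spacer_ref: str,
    mismatch_positions: list[int] | tuple[int, ...],
    tss_offset: int | None = None,
    near_gene: TssRecord | str | None = None,
    rule: RuleSet | None = None,
    promoter_half_width: int = 2000,
    max_tries: int = 100,
    ensure_unique: bool = True,
) -> TruthEntry:
    """Plant an off-target decoy derived from ``spacer_ref``.

    The decoy substitutes the complement base at each listed PAM-proximal
    position.  With ``near_gene`` and ``tss_offset`` the decoy is placed
    at that gene-strand-relative offset; otherwise at a random
    non-colliding locus (bounded retries).  ``ensure_unique=False`` allows
    deliberately identical copies of one decoy at several loci.  The truth
    entry records the expected effective mismatch count and promoter-filter
    fate under ``rule`` (default: the Cascade rule).
    """
    rule = rule or cascade_rule(len(spacer_ref))
    positions = tuple(sorted(mismatch_positions))
    variant_pp = apply_mismatches(
        spacer_ref if rule.pam_side == "5prime" else spacer_ref[::-1], positions
    )
    variant = variant_pp if rule.pam_side == "5prime" else variant_pp[::-1]
    eff, _ = effective_mismatches(
        spacer_ref if rule.pam_side == "5prime" else spacer_ref[::-1], variant_pp, rule.mask
    )

    if near_gene is not None:
        if tss_offset is None:
            raise ValueError("tss_offset required when near_gene is given")
        gene = _lookup_gene(ds, near_gene)
        anchor = _gene_anchor(gene, tss_offset)
        start, end = _plant_site(
            ds, variant, gene.strand, gene.seq_name, anchor, rule, ensure_unique=ensure_unique
        )
        seq_name, strand, gene_id = gene.seq_name, gene.strand, gene.gene_id
    else:
        if tss_offset is not None:
            raise ValueError("tss_offset without near_gene is ambiguous")
        L, P = len(spacer_ref), len(rule.pam_pattern)
        names = sorted(ds._seqs)
        placed = False
        for _ in range(max_tries):
            seq_name = names[int(ds.rng.integers(len(names)))]
            strand = "+" if ds.rng.integers(2) == 0 else "-"
            margin = L + P + 2
            anchor = int(ds.rng.integers(margin, ds.seq_len(seq_name) - margin))
            try:
                start, end = _plant_site(
                    ds, variant, strand, seq_name, anchor, rule, ensure_unique=ensure_unique
                )
            except PlantingError:
                continue
            placed = True
            break
        if not placed:
            raise PlantingError(f"could not place decoy after {max_tries} attempts")
        gene_id = None

    promoters = build_promoters(ds.tss_records, promoter_half_width, ds.genome()) if ds.tss_records else []
    within = any(
        p.seq_name == seq_name and start < p.end and p.start < end for p in promoters
    ) if promoters else False

    entry = TruthEntry(
        kind="decoy",
        gene_id=gene_id,
        seq_name=seq_name,
        strand=strand,
        start=start,
        end=end,
        spacer_ref=spacer_ref,
        spacer_planted=variant,
        mismatch_positions=positions,
        tss_offset=tss_offset,
        expected_effective=eff,
        detectable=eff <= rule.max_mismatches,
        within_promoter=within,
    )
    ds.truth.append(entry)
    return entry


def random_spacer(rng: np.random.Generator, length: int = 32) -> str:
    """Uniform random A/C/G/T spacer."""
    return "".join(rng.choice(_BASES, size=length))


def write_truth(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, TSS BED6 and the truth manifest TSV.

    Output is deterministic for a given dataset.  Returns the paths
    keyed 'fasta', 'bed', 'truth'.
    """
    from .sequence_io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "bed": outdir / "tss.bed",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(ds.genome(), paths["fasta"])
    write_tss_bed(ds.tss_records, paths["bed"])
    rows = [
        {
            "kind": t.kind,
            "gene_id": t.gene_id if t.gene_id is not None else "",
            "seq_name": t.seq_name,
            "strand": t.strand,
            "start": t.start,
            "end": t.end,
            "spacer_ref": t.spacer_ref,
            "spacer_planted": t.spacer_planted,
            "mismatch_positions": ",".join(map(str, t.mismatch_positions)),
            "tss_offset": t.tss_offset if t.tss_offset is not None else "",
            "expected_effective": t.expected_effective,
            "detectable": t.detectable,
            "within_promoter": "" if t.within_promoter is None else t.within_promoter,
        }
        for t in ds.truth
    ]
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    logger.info("synthetic dataset written to %s (seed=%d)", outdir, ds.seed)
    return paths
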