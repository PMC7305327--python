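"""Run configuration and stage orchestration (design → array → off-target).

:class:`RunConfig` gathers every tunable rule parameter with defaults equal
to the type I-F study conditions: 5'-CC PAM, 32-nt spacers, tolerated
positions {6,12,18,24-32}, ≤4 effective mismatches, ±2 kb promoters,
design range [-500, -100] and optimal window [-200, -100] bp upstream of
the TSS, and 50-75 bp pair spacing.  Configs round-trip through flat YAML;
all outputs are deterministic for a given config + inputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import guide_design, offtarget_search, synthetic_data
from .guide_design import DesignWindows
from .mismatch_model import PositionMask
from .offtarget_search import OffTargetHit, RuleSet, cascade_rule, spcas9_rule
from .sequence_io import GenomeSequences, TssRecord, build_promoters, read_fasta, read_tss

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study conditions."""

    fasta: str | None = None
    tss: str | None = None
    tss_format: str = "bed"
    outdir: str = "."
    pam: str = "CC"
    spacer_len: int = 32
    max_mismatches: int = 4
    promoter_half_width: int = 2000
    design_range: tuple[int, int] = (-500, -100)
    optimal_window: tuple[int, int] = (-200, -100)
    pair_spacing: tuple[int, int] = (50, 75)
    masked_positions: tuple[int, ...] | None = None  # None -> {6,12,18,24..L}
    seed: int = 0

    def validate(self) -> "RunConfig":
        try:
            if self.spacer_len < 6:
                raise ValueError("spacer_len must be >= 6")
            if self.max_mismatches < 0:
                raise ValueError("max_mismatches must be >= 0")
            if self.promoter_half_width <= 0:
                raise ValueError("promoter_half_width must be positive")
            if self.tss_format.lower() not in {"bed", "bed6", "gff", "gff3"}:
                raise ValueError(f"unknown tss_format {self.tss_format!r}")
            self.windows()  # validates window ordering
            self.mask()  # validates masked positions
        except ValueError as exc:
            raise ConfigError(str(exc)) from None
        return self

    def windows(self) -> DesignWindows:
        return DesignWindows(tuple(self.design_range), tuple(self.optimal_window))

    def mask(self) -> PositionMask:
        if self.masked_positions is None:
            return PositionMask.cascade_default(self.spacer_len)
        return PositionMask(
            spacer_len=self.spacer_len,
            masked=frozenset(self.masked_positions),
            seed=PositionMask.cascade_default(self.spacer_len).seed,
        )

    def cascade_ruleset(self) -> RuleSet:
        return RuleSet(
            name="cascade_if",
            spacer_len=self.spacer_len,
            pam_pattern=self.pam,
            pam_side="5prime",
            mask=self.mask(),
            max_mismatches=self.max_mismatches,
        )

    def ruleset(self, name: str) -> RuleSet:
        if name == "cascade_if":
            return self.cascade_ruleset()
        if name == "spcas9":
            return spcas9_rule(self.max_mismatches)
        raise ConfigError(f"unknown rule set {name!r} (expected 'cascade_if' or 'spcas9')")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("design_range", "optimal_window", "pair_spacing"):
            data[key] = list(data[key])
        if data["masked_positions"] is not None:
            data["masked_positions"] = sorted(data["masked_positions"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from None
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} is not a key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("design_range", "optimal_window", "pair_spacing"):
            if key in data:
                data[key] = tuple(data[key])
        if data.get("masked_positions") is not None:
            data["masked_positions"] = tuple(data["masked_positions"])
        return cls(**data).validate()

    def config_hash(self) -> str:
        data = asdict(self)
        canon = yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()},
            sort_keys=True,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _load_inputs(config: RunConfig) -> tuple[GenomeSequences, list[TssRecord]]:
    if not config.fasta or not config.tss:
        raise ConfigError("both a FASTA and a TSS annotation path are required")
    try:
        genome = read_fasta(config.fasta)
        tss = read_tss(config.tss, config.tss_format, genome=genome)
    except FileNotFoundError as exc:
        raise ConfigError(f"input not found: {exc}") from None
    except ValueError as exc:
        raise DataError(str(exc)) from None
    if not tss:
        raise DataError(f"no usable TSS records in {config.tss}")
    return genome, tss


def candidates_frame(candidates: list[guide_design.GuideCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "seq_name": c.seq_name,
                "strand": c.strand,
                "start": c.protospacer_start,
                "end": c.protospacer_end,
                "pam": c.pam,
                "spacer": c.spacer,
                "tss_offset": c.tss_offset,
                "window_class": c.window_class,
                "csy3_copies": c.csy3_copies,
            }
            for c in candidates
        ],
        columns=[
            "gene_id", "seq_name", "strand", "start", "end", "pam", "spacer",
            "tss_offset", "window_class", "csy3_copies",
        ],
    )


def run_design(
    config: RunConfig,
    genome: GenomeSequences | None = None,
    tss: list[TssRecord] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Design guide candidates and pairs; write TSV + BED to the outdir.

    Returns the candidate and pair tables.  Candidates are ranked per gene
    (optimal window first); pairs are enumerated per gene.
    """
    config.validate()
    if genome is None or tss is None:
        genome, tss = _load_inputs(config)
    logger.info("design: config %s seed %d", config.config_hash(), config.seed)
    windows = config.windows()
    try:
        candidates = guide_design.extract_candidates(
            genome, tss, config.spacer_len, windows, pam=config.pam
        )
    except (ValueError, KeyError) as exc:
        raise DataError(str(exc)) from None
    ranked: list[guide_design.GuideCandidate] = []
    pair_rows = []
    for gene in tss:
        gene_cands = [c for c in candidates if c.gene_id == gene.gene_id]
        ranked.extend(guide_design.rank_candidates(gene_cands, windows))
        for p in guide_design.select_pairs(gene_cands, config.pair_spacing):
            pair_rows.append(
                {
                    "gene_id": p.first.gene_id,
                    "seq_name": p.first.seq_name,
                    "first_start": p.first.protospacer_start,
                    "second_start": p.second.protospacer_start,
                    "spacing": p.spacing,
                    "spacing_class": p.spacing_class,
                }
            )
    cand_df = candidates_frame(ranked)
    pair_df = pd.DataFrame(
        pair_rows,
        columns=["gene_id", "seq_name", "first_start", "second_start", "spacing", "spacing_class"],
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cand_df.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    pair_df.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    with open(outdir / "candidates.bed", "w") as fh:
        for i, c in enumerate(ranked):
            fh.write(
                f"{c.seq_name}\t{c.protospacer_start}\t{c.protospacer_end}\t"
                f"{c.gene_id}_{i}\t0\t{c.strand}\n"
            )
    return cand_df, pair_df


def run_offtarget(
    config: RunConfig,
    spacers: dict[str, str],
    rule_name: str = "cascade_if",
    genome: GenomeSequences | None = None,
    tss: list[TssRecord] | None = None,
) -> dict[str, list[OffTargetHit]]:
    """Enumerate (and promoter-filter, when TSS are available) off-targets.

    Writes one TSV per query spacer plus a merged BED.  Without TSS
    annotations the hits are reported unfiltered with a warning.
    """
    config.validate()
    rule = config.ruleset(rule_name)
    if genome is None:
        if not config.fasta:
            raise ConfigError("a FASTA path is required")
        try:
            genome = read_fasta(config.fasta)
        except FileNotFoundError as exc:
            raise ConfigError(f"input not found: {exc}") from None
    if tss is None and config.tss:
        tss = read_tss(config.tss, config.tss_format, genome=genome)
    promoters = build_promoters(tss, config.promoter_half_width, genome) if tss else None
    if promoters is None:
        logger.warning("no TSS annotations: off-target hits are reported unfiltered")
    logger.info("offtarget: rule %s, config %s seed %d", rule.name, config.config_hash(), config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, list[OffTargetHit]] = {}
    merged: list[tuple[str, OffTargetHit]] = []
    for label in sorted(spacers):
        try:
            hits = offtarget_search.enumerate_offtargets(spacers[label], genome, rule)
        except ValueError as exc:
            raise DataError(f"spacer {label!r}: {exc}") from None
        if promoters is not None:
            hits = offtarget_search.promoter_filter(hits, promoters)
        results[label] = hits
        offtarget_search.report(hits, outdir / f"offtargets_{label}.tsv", "tsv", rule.pam_side)
        merged.extend((label, h) for h in hits)
    with open(outdir / "offtargets.bed", "w") as fh:
        for label, h in sorted(merged, key=lambda t: (t[1].seq_name, t[1].protospacer_start, t[1].strand, t[0])):
            fh.write(
                f"{h.seq_name}\t{h.protospacer_start}\t{h.protospacer_end}\t"
                f"{label}\t{h.effective_count}\t{h.strand}\n"
            )
    return results


def run_simulate(
    config: RunConfig,
    n_genes: int = 3,
    n_decoys: int = 6,
    length: int = 20_000,
    gc: float = synthetic_data.DEFAULT_GC,
) -> synthetic_data.SyntheticDataset:
    """Generate a planted dataset and write FASTA/BED/truth to the outdir.

    Each gene gets one on-target guide in the optimal window plus decoys
    derived from the first gene's spacer: alternating masked-only,
    seed-heavy and random-position mismatch patterns at random loci.
    """
    config.validate()
    ds = synthetic_data.generate_genome(1, length, gc, config.seed)
    rule = config.cascade_ruleset()
    spacing = length // (n_genes + 1)
    genes = []
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            plant := synthetic_data.plant_gene(ds, "chr1", spacing * (i + 1), strand, f"gene{i + 1}")
        )
        spacer = synthetic_data.random_spacer(ds.rng, config.spacer_len)
        synthetic_data.plant_on_target(ds, plant, spacer, -150, rule)
    ref = ds.truth[0].spacer_ref
    masked = sorted(rule.mask.masked)
    unmasked = [p for p in range(1, config.spacer_len + 1) if p not in rule.mask.masked]
    seen_variants: set[tuple[int, ...]] = set()
    for i in range(n_decoys):
        if i % 3 == 0:
            off = (i // 3) % max(1, len(masked) - 2)
            positions = masked[off : off + 3]
        elif i % 3 == 1:
            width = config.max_mismatches + 1
            off = (i // 3) % max(1, len(unmasked) - width + 1)
            positions = unmasked[off : off + width]
        else:
            # >=1 substitution so the decoy never duplicates the planted
            # on-target; re-draw if the pattern repeats (identical variants
            # cannot pass the generator's duplicate-site check)
            for _ in range(20):
                k = int(ds.rng.integers(1, config.max_mismatches + 2))
                pool = ds.rng.permutation(config.spacer_len) + 1
                positions = sorted(int(p) for p in pool[:k])
                if tuple(positions) not in seen_variants:
                    break
        if tuple(positions) in seen_variants:
            continue
        seen_variants.add(tuple(positions))
        synthetic_data.plant_decoy(
            ds, ref, positions, rule=rule, promoter_half_width=config.promoter_half_width
        )
    synthetic_data.write_truth(ds, config.outdir)
    return ds


def evaluate_dataset(ds: synthetic_data.SyntheticDataset, config: RunConfig) -> pd.DataFrame:
    """Run the full pipeline on a planted dataset and score it against truth.

    For each truth entry: on-targets must be recovered exactly once by
    candidate extraction; decoys must appear in the off-target enumeration
    iff detectable, and survive the promoter filter iff within a promoter.
    Returns one row per entry with expected/observed flags and ``correct``.
    """
    config.validate()
    genome = ds.genome()
    rule = config.cascade_ruleset()
    windows = config.windows()
    promoters = build_promoters(ds.tss_records, config.promoter_half_width, genome)
    candidates = guide_design.extract_candidates(
        genome, ds.tss_records, config.spacer_len, windows, pam=config.pam
    )
    hit_cache: dict[str, list[OffTargetHit]] = {}
    rows = []
    for t in ds.truth:
        if t.kind == "on_target":
            matches = [
                c for c in candidates
                if c.gene_id == t.gene_id and c.protospacer_start == t.start and c.strand == t.strand
            ]
            observed = len(matches) == 1
            expected = True
            retained_obs = retained_exp = None
        else:
            if t.spacer_ref not in hit_cache:
                hit_cache[t.spacer_ref] = offtarget_search.enumerate_offtargets(t.spacer_ref, genome, rule)
            hits = hit_cache[t.spacer_ref]
            at_locus = [
                h for h in hits
                if h.seq_name == t.seq_name and h.protospacer_start == t.start and h.strand == t.strand
            ]
            observed = len(at_locus) == 1
            expected = t.detectable
            filtered = offtarget_search.promoter_filter(at_locus, promoters)
            retained_obs = bool(filtered)
            retained_exp = bool(t.detectable and t.within_promoter)
        rows.append(
            {
                "kind": t.kind,
                "seq_name": t.seq_name,
                "start": t.start,
                "strand": t.strand,
                "expected_detected": expected,
                "observed_detected": observed,
                "expected_retained": retained_exp,
                "observed_retained": retained_obs,
                "correct": (observed == expected)
                and (retained_exp is None or retained_obs == retained_exp),
            }
        )
    return pd.DataFrame(rows)
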