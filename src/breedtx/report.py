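"""Pipeline orchestration and printed-summary arithmetic.

``alignment_summary`` and ``divergence_summary`` reproduce the
percentage arithmetic of the study-style report tables (half-up
rounding at the printed precision). ``run_pipeline`` drives the whole
chain — pileup, site calling, cross-breed divergence, abundance/DE,
and differential splicing — from a config, writing every table plus a
machine-readable run summary; identical config and seed reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .divergence import (
    EffectAnnotator,
    cross_breed_differences,
    differences_table,
    genes_with_cds_coverage,
)
from .expression import (
    count_compatible_fragments,
    de_test,
    detect_breed_specific,
    em_isoform_abundance,
    gene_counts,
    upper_quartile_normalize,
)
from .genome import GeneAnnotation, read_fasta
from .pileup import (
    CallingThresholds,
    build_pileup,
    call_all,
    write_polymorphic_vcf,
    write_site_calls,
)
from .splicing import (
    classify_events,
    diff_splicing_screen,
    events_table,
    single_tss_multi_isoform,
    write_events_bed,
)

log = logging.getLogger(__name__)


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (the convention of printed report tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def alignment_summary(
    total: int, mapped: int, unique: int, decimals: int = 1
) -> tuple[float, float]:
    """(percent mapped of total, percent uniquely mapped of mapped)."""
    if total <= 0:
        raise ValueError("total fragments must be positive")
    if not 0 <= unique <= mapped <= total:
        raise ValueError("expect 0 <= unique <= mapped <= total")
    pct_mapped = round_half_up(100.0 * mapped / total, decimals)
    pct_unique = round_half_up(100.0 * unique / mapped, decimals) if mapped else 0.0
    return pct_mapped, pct_unique


def divergence_summary(n_diff: int, n_denominator: int, decimals: int = 3) -> float:
    """Percentage of differing bases at the printed precision."""
    if n_denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= n_diff <= n_denominator:
        raise ValueError("expect 0 <= n_diff <= n_denominator")
    return round_half_up(100.0 * n_diff / n_denominator, decimals)


@dataclass
class PipelineConfig:
    sam_paths: dict[str, str]  # breed -> SAM path
    reference_fasta: str
    annotation_gtf: str
    out_dir: str
    thresholds: CallingThresholds = field(default_factory=CallingThresholds)
    min_fold: float = 2.0
    max_q: float = 0.05
    detect_threshold: float = 0.0
    cds_cov_min_frac: float = 0.5
    cds_cov_min_depth: int = 10
    intergenic_min_dist: int = 1000
    n_boot: int = 10000
    seed: int = 0

    def validate(self) -> None:
        missing = [
            p for p in [self.reference_fasta, self.annotation_gtf, *self.sam_paths.values()]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")
        if not self.sam_paths:
            raise ValueError("at least one breed SAM is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = CallingThresholds(**thr)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sam_alignment_tallies(sam_path) -> dict:
    """Fragment tallies from SAM flags/NH tags: total, mapped, unique."""
    import pysam

    total_frags: set[str] = set()
    mapped_frags: set[str] = set()
    unique_frags: set[str] = set()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_secondary or read.is_supplementary:
                continue
            total_frags.add(read.query_name)
            if not read.is_unmapped:
                mapped_frags.add(read.query_name)
                if not read.has_tag("NH") or read.get_tag("NH") == 1:
                    unique_frags.add(read.query_name)
    return {
        "total_fragments": len(total_frags),
        "mapped_fragments": len(mapped_frags),
        "uniquely_mapped_fragments": len(unique_frags),
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run pileup -> calling -> divergence -> expression -> splicing -> report.

    Every stage writes its tables under ``config.out_dir``; a JSON run
    summary and a plain-text log close the run. Raises
    :class:`StageError` naming the failing stage; a partial-output
    manifest is written before the error propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    breeds = list(config.sam_paths)
    manifest: list[str] = []
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "breeds": breeds,
        "notes": ["sequence-bias correction not applied (out of scope)"],
    }
    log_lines: list[str] = [f"breedtx {__version__} run, seed={config.seed}"]

    def record(path: Path) -> Path:
        manifest.append(path.name)
        return path

    def fail(stage: str, exc: Exception):
        (out / "manifest.json").write_text(json.dumps({"outputs": manifest}, indent=2))
        raise StageError(stage, exc) from exc

    try:
        reference = read_fasta(config.reference_fasta)
        annotation = GeneAnnotation.read_gtf(
            config.annotation_gtf, {c: len(s) for c, s in reference.items()}
        )
    except Exception as exc:  # noqa: BLE001
        fail("load_inputs", exc)

    # ---- pileup + calling
    tables = {}
    calls = {}
    summary["alignment"] = {}
    summary["calling"] = {}
    try:
        for breed in breeds:
            tally = _sam_alignment_tallies(config.sam_paths[breed])
            pm, pu = (
                alignment_summary(
                    tally["total_fragments"], tally["mapped_fragments"],
                    tally["uniquely_mapped_fragments"],
                )
                if tally["mapped_fragments"]
                else (0.0, 0.0)
            )
            tally["percent_mapped"] = pm
            tally["percent_uniquely_mapped"] = pu
            summary["alignment"][breed] = tally
            table = build_pileup(config.sam_paths[breed], config.thresholds, breed=breed)
            tables[breed] = table
            breed_calls, breed_summary = call_all(table, config.thresholds)
            calls[breed] = breed_calls
            summary["calling"][breed] = breed_summary
            write_site_calls(breed_calls, record(out / f"site_calls_{breed}.tsv"))
            write_polymorphic_vcf(
                breed_calls, table, reference, record(out / f"polymorphic_{breed}.vcf")
            )
            log_lines.append(
                f"{breed}: {table.n_fragments} fragments piled, "
                f"{table.n_skipped} records skipped"
            )
    except Exception as exc:  # noqa: BLE001
        fail("pileup_calling", exc)

    # ---- divergence
    if len(breeds) >= 2:
        try:
            diffs, pair_counts, n_det = cross_breed_differences(calls)
            annotator = EffectAnnotator(annotation, reference)
            diffs = [annotator.annotate(d) for d in diffs]
            differences_table(diffs, breeds).to_csv(
                record(out / "differences.tsv"), sep="\t", index=False
            )
            pair_rows = [
                {
                    "breed_a": a, "breed_b": b, "n_differences": n,
                    "percent": divergence_summary(n, n_det, 3) if n_det else 0.0,
                }
                for (a, b), n in pair_counts.items()
            ]
            pd.DataFrame(pair_rows).to_csv(
                record(out / "pairwise_differences.tsv"), sep="\t", index=False
            )
            summary["divergence"] = {
                "n_determinable": n_det,
                "pairs": {f"{a}|{b}": n for (a, b), n in pair_counts.items()},
            }
            covered = {
                breed: sorted(
                    genes_with_cds_coverage(
                        annotation, tables[breed],
                        config.cds_cov_min_frac, config.cds_cov_min_depth,
                    )
                )
                for breed in breeds
            }
            pd.DataFrame(
                [{"breed": b, "gene": g} for b in breeds for g in covered[b]]
            ).to_csv(record(out / "genes_cds_covered.tsv"), sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            fail("divergence", exc)
    else:
        log_lines.append("single breed: divergence stage skipped")
        summary["divergence"] = "skipped (single breed)"

    # ---- expression
    try:
        abundances = {}
        compat = {}
        for breed in breeds:
            compat[breed] = count_compatible_fragments(
                config.sam_paths[breed], annotation, breed=breed
            )
            abundances[breed] = em_isoform_abundance(compat[breed], annotation)
        pd.concat(abundances.values(), ignore_index=True).to_csv(
            record(out / "abundance.tsv"), sep="\t", index=False
        )
        counts = pd.DataFrame({b: gene_counts(abundances[b]) for b in breeds}).fillna(0.0)
        normalized, scales = upper_quartile_normalize(counts)
        pd.DataFrame(
            {
                "breed": breeds,
                "library_size": [compat[b].library_size for b in breeds],
                "uq_scale": [scales[b] for b in breeds],
            }
        ).to_csv(record(out / "library_scales.tsv"), sep="\t", index=False)
        fpkm = pd.DataFrame(
            {
                b: abundances[b].drop_duplicates("gene").set_index("gene")["gene_fpkm"]
                for b in breeds
            }
        ).fillna(0.0)
        specific = detect_breed_specific(fpkm, config.detect_threshold)
        summary["expression"] = {
            b: {
                "detected": len(specific[b]["detected"]),
                "specific": len(specific[b]["specific"]),
            }
            for b in breeds
        }
        de_results = {}
        for a, b in itertools.combinations(breeds, 2):
            de = de_test(
                counts[a], counts[b],
                compat[a].library_size, compat[b].library_size,
                min_fold=config.min_fold, max_q=config.max_q,
            )
            de.to_csv(record(out / f"de_{a}_vs_{b}.tsv"), sep="\t", index=False)
            de_results[(a, b)] = de
        summary["de"] = {
            f"{a}|{b}": int(de["significant"].sum()) for (a, b), de in de_results.items()
        }
    except Exception as exc:  # noqa: BLE001
        fail("expression", exc)

    # ---- splicing
    try:
        tss_groups = single_tss_multi_isoform(annotation)
        all_events = [
            ev for gene in sorted(tss_groups) for ev in classify_events(annotation, gene)
        ]
        events_table(all_events).to_csv(
            record(out / "splice_events.tsv"), sep="\t", index=False
        )
        contig_of = {g: annotation.gene_span(g)[0] for g in tss_groups}
        write_events_bed(all_events, contig_of, record(out / "splice_events.bed"))
        summary["splicing"] = {
            "n_single_tss_multi_isoform_genes": len(tss_groups),
            "n_events": len(all_events),
        }
        if len(breeds) >= 2:
            iso_counts = {
                breed: abundances[breed].set_index("transcript")["expected_count"]
                for breed in breeds
            }
            for a, b in itertools.combinations(breeds, 2):
                usage_counts = {}
                for gene, tids in tss_groups.items():
                    usage_counts[gene] = (
                        np.array([iso_counts[a].get(t, 0.0) for t in tids]),
                        np.array([iso_counts[b].get(t, 0.0) for t in tids]),
                    )
                screen = diff_splicing_screen(
                    usage_counts, n_boot=config.n_boot, seed=config.seed
                )
                screen.to_csv(
                    record(out / f"diff_splicing_{a}_vs_{b}.tsv"), sep="\t", index=False
                )
        else:
            log_lines.append("single breed: splicing comparison skipped")
    except Exception as exc:  # noqa: BLE001
        fail("splicing", exc)

    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest.append("run_summary.json")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest.append("run.log")
    (out / "manifest.json").write_text(json.dumps({"outputs": sorted(manifest)}, indent=2))
    return out
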