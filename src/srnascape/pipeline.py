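"""End-to-end orchestration of the analysis stages with provenance.

``run_all`` executes io → loci → categories → trf → te_meth →
periodicity → hairpin on either a synthetic bundle or external input
files, writes every stage's output as TSV/BED/JSON, and records a
manifest with parameters, seeds and SHA-256 hashes of all outputs so a
rerun with the same configuration can be verified byte-for-byte.  Stage
outputs are pure functions of (inputs, parameters, seed); stages whose
optional inputs are missing are skipped with a warning rather than
failing the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import categories, hairpin, io_coverage, loci, periodicity, te_meth, trf
from .io_coverage import AnnotationSet, compute_coverage, in_range
from .synthetic import Bundle, SyntheticConfig, generate, truth_compare

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger("srnascape")


@dataclass
class RunConfig:
    """Inputs and per-stage parameters of a full pipeline run."""

    outdir: str = "srnascape_out"
    seed: int = 17
    # external inputs (ignored when synthetic=True)
    synthetic: bool = True
    genome: Optional[str] = None
    alignments: dict = field(default_factory=dict)  # library -> BAM/BED path
    gff: Optional[str] = None
    methylation: Optional[str] = None
    trna_table: Optional[str] = None
    expression: Optional[str] = None
    # stage parameters
    max_gap: int = loci.DEFAULT_MAX_GAP
    min_reads: int = loci.DEFAULT_MIN_READS
    category_mode: str = "partition"
    window: int = periodicity.DEFAULT_WINDOW
    step: int = periodicity.DEFAULT_STEP
    sig_fraction: float = periodicity.DEFAULT_SIG_FRACTION
    span: int = periodicity.DEFAULT_SPAN
    min_significant: int = periodicity.DEFAULT_MIN_SIGNIFICANT
    hairpin_flank: int = hairpin.DEFAULT_FLANK
    hairpin_n_permutations: int = hairpin.DEFAULT_N_PERMUTATIONS
    hairpin_max_candidates: int = 20
    folding_temperature: float = 24.0
    folding_backend: str = "auto"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns a report dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"warnings": [], "stages": {}}
    outputs: dict[str, Path] = {}

    # --- stage: io ----------------------------------------------------------
    try:
        if config.synthetic:
            bundle = generate(SyntheticConfig(seed=config.seed))
            genome = bundle.genome
            annotations = bundle.annotations
            reads_per_library = bundle.reads
            expression_df = bundle.expression
            bundle_paths = bundle.write(outdir / "inputs")
            outputs.update({f"input_{k}": v for k, v in bundle_paths.items()})
        else:
            bundle = None
            if not config.genome or not config.alignments:
                raise ValueError("non-synthetic runs need genome and alignments")
            genome = io_coverage.load_genome(config.genome)
            chrom_sizes = {c: len(s) for c, s in genome.items()}
            annotations = io_coverage.load_annotations(
                genome, config.gff, config.methylation, config.trna_table
            )
            reads_per_library = {
                lib: io_coverage.load_alignments(path, lib, chrom_sizes=chrom_sizes)
                for lib, path in config.alignments.items()
            }
            expression_df = (
                pd.read_csv(config.expression, sep="\t") if config.expression else None
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'io' failed: {exc}") from exc

    chrom_sizes = {c: len(s) for c, s in genome.items()}
    all_reads = [r for lib in sorted(reads_per_library) for r in reads_per_library[lib]]
    usable = in_range(all_reads)
    report["stages"]["io"] = {
        "n_reads": len(all_reads),
        "n_in_range": len(usable),
        "libraries": sorted(reads_per_library),
    }

    # --- stage: loci --------------------------------------------------------
    try:
        detected = loci.cluster_srna_loci(
            usable, max_gap=config.max_gap, min_reads=config.min_reads
        )
        classes = [loci.classify_distribution(l) for l in detected]
        candidates_per_lib = {
            lib: loci.filter_candidates(
                [
                    l
                    for l in loci.cluster_srna_loci(
                        in_range(reads_per_library[lib]),
                        max_gap=config.max_gap,
                        min_reads=config.min_reads,
                    )
                    if loci.classify_distribution(l) == "PILE"
                ],
                genome,
                annotations,
            )
            for lib in reads_per_library
        }
        merged = loci.merge_across_libraries(candidates_per_lib)
        outputs["loci_bed"] = outdir / "loci.bed"
        loci.loci_to_bed(detected, outputs["loci_bed"], classes)
        cand_df = pd.DataFrame(
            {
                "chrom": [c.chrom for c in merged],
                "start": [c.start for c in merged],
                "end": [c.end for c in merged],
                "type": [c.candidate_type for c in merged],
                "support": [c.support for c in merged],
                "libraries": [",".join(sorted(c.libraries)) for c in merged],
                "read_count": [c.locus.read_count for c in merged],
                "dominant_length": [c.locus.dominant_length for c in merged],
            }
        )
        outputs["candidates_tsv"] = outdir / "candidates.tsv"
        cand_df.to_csv(outputs["candidates_tsv"], sep="\t", index=False)
        report["stages"]["loci"] = {
            "n_loci": len(detected),
            "n_pile": sum(c == "PILE" for c in classes),
            "n_candidates": len(merged),
            "n_multi_library": sum(c.support >= 2 for c in merged),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'loci' failed: {exc}") from exc

    # --- stage: categories --------------------------------------------------
    try:
        summary = categories.summary_table(
            reads_per_library, annotations, mode=config.category_mode
        )
        outputs["category_summary"] = outdir / "category_summary.tsv"
        summary.to_csv(outputs["category_summary"], sep="\t")
        lengths = categories.length_distribution(
            usable, by="category", annotations=annotations
        )
        outputs["length_histogram"] = outdir / "length_histogram.tsv"
        lengths.to_csv(outputs["length_histogram"], sep="\t")
        report["stages"]["categories"] = {
            "aligned_total": int(summary.loc["aligned", "total"]),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'categories' failed: {exc}") from exc

    # --- stage: trf ---------------------------------------------------------
    if annotations.trnas:
        try:
            records = trf.classify_reads(usable, annotations.trnas)
            table = trf.trf_table(records)
            outputs["trf_table"] = outdir / "trf_table.tsv"
            table.to_csv(outputs["trf_table"], sep="\t", index=False)
            report["stages"]["trf"] = {
                "n_fragments": len(records),
                "n_classes": int(table["class"].nunique()) if len(table) else 0,
            }
        except Exception as exc:
            raise RuntimeError(f"stage 'trf' failed: {exc}") from exc
    else:
        report["warnings"].append("no tRNA annotations; trf stage skipped")

    # --- stage: te_meth -----------------------------------------------------
    if annotations.repeats:
        try:
            expr_map, est_map, gene_ref = {}, {}, None
            if expression_df is not None:
                expr_map = dict(zip(expression_df["name"], expression_df["rnaseq"]))
                if "est_count" in expression_df:
                    est_map = dict(zip(expression_df["name"], expression_df["est_count"]))
                if "kind" in expression_df:
                    gene_ref = expression_df.loc[
                        expression_df["kind"] == "gene", "rnaseq"
                    ].tolist() or None
            stats_list = te_meth.region_stats_table(
                annotations.repeats, usable, total_aligned=len(usable),
                probes=annotations.methylation, expression=expr_map,
                est_counts=est_map, reference_expressions=gene_ref,
            )
            outputs["te_stats"] = outdir / "te_stats.tsv"
            te_meth.stats_to_frame(stats_list).to_csv(
                outputs["te_stats"], sep="\t", index=False
            )
            assoc = te_meth.association_tests(stats_list, reads_per_library)
            comp = te_meth.five_prime_composition(
                [
                    r
                    for r in usable
                    if categories.assign_category(r, annotations) == "repeats"
                ]
            )
            outputs["five_prime_composition"] = outdir / "five_prime_composition.tsv"
            comp.to_csv(outputs["five_prime_composition"], sep="\t")
            lib_corr = assoc.pop("library_correlation", None)
            if lib_corr is not None:
                outputs["library_correlation"] = outdir / "library_correlation.tsv"
                lib_corr.to_csv(outputs["library_correlation"], sep="\t")
            outputs["association_tests"] = outdir / "association_tests.json"
            with open(outputs["association_tests"], "w") as fh:
                json.dump(assoc, fh, indent=2, default=_json_default, sort_keys=True)
            report["stages"]["te_meth"] = assoc
        except Exception as exc:
            raise RuntimeError(f"stage 'te_meth' failed: {exc}") from exc
    else:
        report["warnings"].append("no repeat annotations; te_meth stage skipped")

    # --- stage: periodicity -------------------------------------------------
    try:
        tracks = compute_coverage(usable, chrom_sizes, mode="reweighted")
        windows = periodicity.scan(
            tracks, window=config.window, step=config.step,
            sig_fraction=config.sig_fraction,
        )
        regions = periodicity.call_periodic_regions(
            windows, span=config.span, min_significant=config.min_significant
        )
        outputs["period_windows"] = outdir / "period_windows.bed"
        periodicity.windows_to_bed(windows, outputs["period_windows"])
        outputs["periodic_regions"] = outdir / "periodic_regions.bed"
        periodicity.regions_to_bed(regions, outputs["periodic_regions"])
        sig = [w for w in windows if w.significant]
        periods = [round(w.main_period) for w in sig if w.main_period]
        modal = (
            int(pd.Series(periods).mode().iloc[0]) if periods else None
        )
        stage: dict = {
            "n_windows": len(windows),
            "n_significant": len(sig),
            "n_regions": len(regions),
            "modal_period": modal,
        }
        if annotations.methylation:
            # HMRs: merge methylated probe positions within 200 nt
            meth_probes = [
                p for p in annotations.methylation if p.attrs.get("methylated")
            ]
            hmrs = _merge_probe_intervals(meth_probes, gap=200)
            stage["hmr_overlap"] = periodicity.hmr_overlap(regions, hmrs, detected)
        report["stages"]["periodicity"] = stage
    except Exception as exc:
        raise RuntimeError(f"stage 'periodicity' failed: {exc}") from exc

    # --- stage: hairpin -----------------------------------------------------
    try:
        results = []
        rng = np.random.default_rng(config.seed)
        for idx, cand in enumerate(merged[: config.hairpin_max_candidates]):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            hp = hairpin.evaluate_candidate(
                cand.chrom, cand.start, cand.end, cand.locus.strand,
                cand.locus.reads, genome,
                flank=config.hairpin_flank,
                n_permutations=config.hairpin_n_permutations,
                seed=sub_seed,
                temperature=config.folding_temperature,
                backend=config.folding_backend,
            )
            results.append(
                {
                    "chrom": hp.chrom, "start": hp.start, "end": hp.end,
                    "strand": hp.strand, "structure": hp.structure,
                    "mfe": hp.mfe, "empirical_p": hp.empirical_p,
                    "significant": hp.significant,
                    "overhang_status": hp.overhang_status,
                    "verdict": hp.verdict, "backend": hp.backend,
                    "temperature": hp.temperature, "seed": hp.seed,
                    "n_matures": len(hp.matures),
                }
            )
        outputs["hairpins"] = outdir / "hairpins.json"
        with open(outputs["hairpins"], "w") as fh:
            json.dump(results, fh, indent=2, default=_json_default, sort_keys=True)
        report["stages"]["hairpin"] = {
            "n_evaluated": len(results),
            "n_mirna_like": sum(r["verdict"] == "miRNA_like" for r in results),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'hairpin' failed: {exc}") from exc

    # --- truth comparison (synthetic runs) ----------------------------------
    if config.synthetic and bundle is not None:
        piles = [l for l, c in zip(detected, classes) if c == "PILE"]
        recovery = truth_compare(
            piles, bundle.truth["loci"],
            detected_classes=["PILE"] * len(piles), kind="pile",
        )
        report["stages"]["truth_compare"] = recovery

    # --- manifest -----------------------------------------------------------
    manifest = {
        "package": "srnascape",
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report["manifest"] = manifest
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default, sort_keys=True)
    return report


def _merge_probe_intervals(probes, gap: int = 200):
    """Merge probe positions closer than ``gap`` into HMR-like intervals."""
    from .io_coverage import Feature

    by_chrom: dict[str, list] = {}
    for p in probes:
        by_chrom.setdefault(p.chrom, []).append(p)
    hmrs = []
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom], key=lambda p: p.start)
        start, end = ps[0].start, ps[0].end
        for p in ps[1:]:
            if p.start - end < gap:
                end = max(end, p.end)
            else:
                hmrs.append(Feature(chrom=chrom, start=start, end=end, name="HMR"))
                start, end = p.start, p.end
        hmrs.append(Feature(chrom=chrom, start=start, end=end, name="HMR"))
    return hmrs
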