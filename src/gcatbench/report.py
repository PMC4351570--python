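"""Render benchmark results as TSV/JSON tables and optional figure files.

Tables are the contract: every number in a report can be recomputed from
the stored inputs and the serialized run configuration, and every emitted
file embeds a provenance header (package version, config hash, seed).
Plots mirror the benchmark's standard panels — the alignment ROC-like
curve, the MAPQ calibration histogram (log count axis), the variant-quality
ROC and precision versus read depth — and are a headless-safe convenience.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import __version__
from .alneval import AlignmentSummary, CalibrationHistogram, RocCurve
from .vareval import (DepthStratum, MetricSet, QualityRocCurve,
                      VariantComparison)


@dataclass
class RunConfig:
    """Serializable record of one benchmark invocation."""

    subcommand: str
    parameters: dict
    seed: Optional[int] = None
    out_prefix: str = "gcatbench"

    def as_dict(self) -> dict:
        return {"subcommand": self.subcommand, "parameters": self.parameters,
                "seed": self.seed, "out_prefix": self.out_prefix,
                "version": __version__}

    @property
    def digest(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(config: RunConfig) -> list[str]:
    return [
        f"# gcatbench {__version__}",
        f"# config-hash {config.digest} seed {config.seed}",
        f"# config {json.dumps(config.as_dict(), sort_keys=True)}",
    ]


def write_tsv(path: str, header: Sequence[str], rows: Sequence[Sequence],
              config: Optional[RunConfig] = None) -> None:
    with open(path, "w") as fh:
        if config is not None:
            for line in provenance_lines(config):
                fh.write(line + "\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def write_json(path: str, payload: dict,
               config: Optional[RunConfig] = None) -> None:
    doc = dict(payload)
    if config is not None:
        doc["provenance"] = {"version": __version__,
                             "config_hash": config.digest,
                             "config": config.as_dict()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class BenchmarkReport:
    """Aggregated result tables for one run, renderable as TSV/JSON/plots."""

    config: RunConfig
    alignment_summary: Optional[AlignmentSummary] = None
    alignment_roc: Optional[RocCurve] = None
    calibration: Optional[CalibrationHistogram] = None
    comparison: Optional[VariantComparison] = None
    variant_metrics: Optional[MetricSet] = None
    variant_roc: Optional[QualityRocCurve] = None
    depth_strata: Optional[list[DepthStratum]] = None
    extra: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def as_dict(self) -> dict:
        doc: dict = dict(self.extra)
        if self.alignment_summary is not None:
            doc["alignment_summary"] = self.alignment_summary.as_dict()
        if self.alignment_roc is not None:
            doc["alignment_roc"] = [
                {"mapq_threshold": p.threshold, "correct": p.correct,
                 "incorrect": p.incorrect} for p in self.alignment_roc]
        if self.calibration is not None:
            doc["calibration"] = {
                "bin_edges": list(self.calibration.bin_edges),
                "incorrect_counts": list(self.calibration.counts)}
        if self.comparison is not None:
            c = self.comparison
            doc["variant_counts"] = {
                "tp": c.tp_count, "fp": c.fp_count, "fn": c.fn_count,
                "tn_bases": c.tn_count,
                "excluded_test": c.excluded_test_count,
                "excluded_truth": c.excluded_truth_count,
                "genotype_aware": c.genotype_aware}
        if self.variant_metrics is not None:
            doc["variant_metrics"] = self.variant_metrics.as_dict()
            doc.setdefault("notes", []).append(
                "specificity is near-saturated on high-confidence regions; "
                "the precision rate is usually the more informative statistic")
        if self.variant_roc is not None:
            doc["variant_roc"] = [
                {"quality_threshold": p.threshold, "tp": p.tp, "fp": p.fp,
                 "fn": p.fn, "tn": p.tn, "tpr": p.tpr, "fpr": p.fpr}
                for p in self.variant_roc]
        if self.depth_strata is not None:
            doc["depth_strata"] = [
                {"lo": s.lo, "hi": s.hi, "tp": s.tp, "fp": s.fp,
                 "precision": s.precision} for s in self.depth_strata]
        return doc

    # ------------------------------------------------------------------
    def render(self, formats: Sequence[str] = ("tsv", "json")) -> list[str]:
        """Write the report under the config's output prefix; return paths."""
        known = {"tsv", "json", "plots"}
        unknown = set(formats) - known
        if unknown:
            from .errors import InputError
            raise InputError(f"unknown report format(s): {sorted(unknown)}")
        prefix = self.config.out_prefix
        paths: list[str] = []
        if "json" in formats:
            p = f"{prefix}.report.json"
            write_json(p, self.as_dict(), self.config)
            paths.append(p)
        if "tsv" in formats:
            paths.extend(self._render_tsv(prefix))
        if "plots" in formats:
            paths.extend(self._render_plots(prefix))
        return paths

    def _render_tsv(self, prefix: str) -> list[str]:
        paths = []
        if self.alignment_summary is not None:
            s = self.alignment_summary.as_dict()
            p = f"{prefix}.alignment_summary.tsv"
            write_tsv(p, list(s.keys()), [list(s.values())], self.config)
            paths.append(p)
        if self.alignment_roc is not None:
            p = f"{prefix}.alignment_roc.tsv"
            write_tsv(p, ["mapq_threshold", "cumulative_correct",
                          "cumulative_incorrect"],
                      [(pt.threshold, pt.correct, pt.incorrect)
                       for pt in self.alignment_roc], self.config)
            paths.append(p)
        if self.calibration is not None:
            p = f"{prefix}.calibration.tsv"
            edges = self.calibration.bin_edges
            write_tsv(p, ["percentile_lo", "percentile_hi", "incorrect_count"],
                      [(edges[i], edges[i + 1], c)
                       for i, c in enumerate(self.calibration.counts)],
                      self.config)
            paths.append(p)
        if self.comparison is not None or self.variant_metrics is not None:
            p = f"{prefix}.variant_metrics.tsv"
            c, m = self.comparison, self.variant_metrics
            header = ["tp", "fp", "fn", "tn_bases", "excluded_test",
                      "excluded_truth", "precision_pct", "sensitivity_pct",
                      "specificity_pct"]
            md = m.as_dict() if m is not None else {}
            row = [c.tp_count if c else None, c.fp_count if c else None,
                   c.fn_count if c else None, c.tn_count if c else None,
                   c.excluded_test_count if c else None,
                   c.excluded_truth_count if c else None,
                   md.get("precision_pct"), md.get("sensitivity_pct"),
                   md.get("specificity_pct")]
            write_tsv(p, header, [row], self.config)
            paths.append(p)
        if self.variant_roc is not None:
            p = f"{prefix}.variant_roc.tsv"
            write_tsv(p, ["quality_threshold", "tp", "fp", "fn", "tn",
                          "tpr", "fpr"],
                      [(pt.threshold, pt.tp, pt.fp, pt.fn, pt.tn,
                        pt.tpr, pt.fpr) for pt in self.variant_roc],
                      self.config)
            paths.append(p)
        if self.depth_strata is not None:
            p = f"{prefix}.depth_strata.tsv"
            write_tsv(p, ["depth_lo", "depth_hi", "tp", "fp", "precision"],
                      [(s.lo, s.hi, s.tp, s.fp, s.precision)
                       for s in self.depth_strata], self.config)
            paths.append(p)
        return paths

    def _render_plots(self, prefix: str) -> list[str]:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        paths = []
        if self.alignment_roc is not None and len(self.alignment_roc):
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.plot([p.correct for p in self.alignment_roc],
                    [p.incorrect for p in self.alignment_roc],
                    marker=".", lw=1)
            ax.set_xlabel("correctly mapped reads (cumulative)")
            ax.set_ylabel("incorrectly mapped reads (cumulative)")
            ax.set_title("Alignment ROC-like curve (by MAPQ threshold)")
            paths.append(self._save(fig, f"{prefix}.alignment_roc.png"))
        if self.calibration is not None:
            fig, ax = plt.subplots(figsize=(5, 4))
            edges = self.calibration.bin_edges
            centers = [(edges[i] + edges[i + 1]) / 2
                       for i in range(len(edges) - 1)]
            ax.bar(centers, self.calibration.counts,
                   width=(edges[1] - edges[0]) * 0.9)
            ax.set_yscale("symlog")
            ax.set_xlabel("normalized mapping-quality percentile")
            ax.set_ylabel("incorrectly mapped reads (log scale)")
            ax.set_title("Mapping-quality calibration")
            paths.append(self._save(fig, f"{prefix}.calibration.png"))
        if self.variant_roc is not None and len(self.variant_roc):
            fig, ax = plt.subplots(figsize=(5, 4))
            pts = [p for p in self.variant_roc
                   if p.fpr is not None and p.tpr is not None]
            ax.plot([p.fpr for p in pts], [p.tpr for p in pts],
                    marker=".", lw=1)
            ax.set_xlabel("false-positive rate FP/(FP+TN)")
            ax.set_ylabel("true-positive rate TP/(TP+FN)")
            ax.set_title("Variant-quality ROC-like curve")
            paths.append(self._save(fig, f"{prefix}.variant_roc.png"))
        if self.depth_strata:
            fig, ax = plt.subplots(figsize=(5, 4))
            binned = [s for s in self.depth_strata
                      if s.lo is not None and s.precision is not None]
            ax.plot([(s.lo + s.hi) / 2 for s in binned],
                    [100 * s.precision for s in binned], marker="o")
            ax.set_xlabel("read depth")
            ax.set_ylabel("precision (%)")
            ax.set_title("Precision vs read depth")
            paths.append(self._save(fig, f"{prefix}.depth_strata.png"))
        return paths

    @staticmethod
    def _save(fig, path: str) -> str:
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        import matplotlib.pyplot as plt
        plt.close(fig)
        return path
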