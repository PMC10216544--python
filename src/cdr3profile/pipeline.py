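"""End-to-end orchestration: translate -> lengths -> pI -> composition ->
clonality -> immunogenicity -> sharing -> comparison, with per-stage TSV
outputs, figures, and a combined per-sample summary."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from statistics import mean

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .biochem import DEFAULT_PKA, isoelectric_point, load_pka, residue_composition
from .clonality import sample_clonality
from .compare import compare_clone_frequencies
from .immunogenicity import (load_default_model, load_model, score_peptide,
                             summarize_immunogenicity)
from .io import Cohort, read_rearrangements, write_fasta
from .lengths import cohort_length_table, length_distribution, length_summary
from .sharing import conservation_string, shared_clones
from .translate import productive, translate_cohort

log = logging.getLogger(__name__)

ALL_STAGES = ("lengths", "pi", "composition", "clonality", "immunogenicity",
              "shared", "compare")


@dataclass
class PipelineConfig:
    output_dir: Path
    input_path: Path | None = None
    dialect: str = "auto"
    metadata_path: Path | None = None
    stages: tuple[str, ...] = ALL_STAGES
    pka_path: Path | None = None
    weights_path: Path | None = None
    weighted_moments: bool = True
    length_scale: str = "nt"
    make_figures: bool = True


class StageError(RuntimeError):
    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed on sample '{sample}': {cause}")
        self.stage, self.sample = stage, sample


def run_report(config: PipelineConfig, cohort: Cohort | None = None) -> Path:
    """Run the enabled stages over a cohort and write the report bundle.

    ``cohort`` may be passed in memory (e.g. from the simulator); otherwise
    it is read from ``config.input_path``.  Returns the output directory.
    Any stage failure aborts with the stage and sample named; files already
    written are kept and the MANIFEST marks the run incomplete.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "complete": False, "stages": {},
                      "config": {k: str(v) for k, v in vars(config).items()}}
    if cohort is None:
        if config.input_path is None:
            raise ValueError("need either an in-memory cohort or input_path")
        cohort = read_rearrangements(config.input_path, config.dialect,
                                     metadata=config.metadata_path)
    translate_cohort(cohort)
    pka = load_pka(config.pka_path) if config.pka_path else DEFAULT_PKA
    model = load_model(config.weights_path) if config.weights_path \
        else load_default_model()

    summary_rows = {rep.sample_id: {
        "sample_id": rep.sample_id,
        "group": rep.group.value,
        "unique_sequences": len(rep),
        "total_templates": rep.total_templates,
        "productive_sequences": len(productive(rep)),
    } for rep in cohort.repertoires}

    stage = sample = ""
    try:
        for rep in cohort.repertoires:
            sample = rep.sample_id
            write_fasta(rep, out / f"{rep.sample_id}.faa")

        if "lengths" in config.stages:
            stage = "lengths"
            table = cohort_length_table(cohort, scale=config.length_scale)
            table.to_csv(out / "lengths.tsv", sep="\t", index=False)
            rows = []
            for rep in cohort.repertoires:
                sample = rep.sample_id
                dist = length_distribution(rep, scale=config.length_scale)
                if not dist.lengths:
                    continue
                s = length_summary(dist, weighted=config.weighted_moments)
                rows.append({"sample_id": rep.sample_id, "scale": dist.scale,
                             "min_length": dist.min_length,
                             "max_length": dist.max_length, "mean": s.mean,
                             "variance": s.variance, "skewness": s.skewness,
                             "kurtosis": s.kurtosis})
            pd.DataFrame(rows).to_csv(out / "length_summary.tsv", sep="\t",
                                      index=False)
            if config.make_figures:
                _length_figure(cohort, config.length_scale,
                               out / "length_distributions.png")
            manifest["stages"]["lengths"] = "ok"

        if "pi" in config.stages:
            stage = "pi"
            rows = []
            for rep in cohort.repertoires:
                sample = rep.sample_id
                for r in productive(rep):
                    rows.append({"sample_id": rep.sample_id, "cdr3_aa": r.cdr3_aa,
                                 "pI": isoelectric_point(r.cdr3_aa, pka).pI})
                    summary_rows[rep.sample_id].setdefault("_pis", []).append(
                        rows[-1]["pI"])
            pd.DataFrame(rows).to_csv(out / "isoelectric_points.tsv", sep="\t",
                                      index=False)
            for sid, row in summary_rows.items():
                pis = row.pop("_pis", [])
                row["mean_pI"] = mean(pis) if pis else float("nan")
            manifest["stages"]["pi"] = "ok"

        if "composition" in config.stages:
            stage = "composition"
            frames = []
            by_group: dict[str, list[str]] = {}
            for rep in cohort.repertoires:
                sample = rep.sample_id
                peps = [r.cdr3_aa for r in productive(rep)]
                if not peps:
                    continue
                df = residue_composition(peps).to_frame()
                df.insert(0, "scope", rep.sample_id)
                frames.append(df)
                by_group.setdefault(rep.group.value, []).extend(peps)
            for gname, peps in by_group.items():
                df = residue_composition(peps).to_frame()
                df.insert(0, "scope", f"group:{gname}")
                frames.append(df)
            pd.concat(frames, ignore_index=True).to_csv(
                out / "composition.tsv", sep="\t", index=False)
            manifest["stages"]["composition"] = "ok"

        if "clonality" in config.stages:
            stage = "clonality"
            rows = []
            for rep in cohort.repertoires:
                sample = rep.sample_id
                c = sample_clonality(rep)
                rows.append({"sample_id": c.sample_id, "group": rep.group.value,
                             "n_clones": c.n_clones,
                             "simpson_index": c.simpson_index,
                             "clonality": c.clonality})
                summary_rows[rep.sample_id]["clonality"] = c.clonality
            df = pd.DataFrame(rows)
            df.to_csv(out / "clonality.tsv", sep="\t", index=False)
            if config.make_figures:
                _clonality_figure(df, out / "clonality.png")
            manifest["stages"]["clonality"] = "ok"

        if "immunogenicity" in config.stages:
            stage = "immunogenicity"
            rows = []
            for rep in cohort.repertoires:
                sample = rep.sample_id
                scores = [score_peptide(r.cdr3_aa, model)
                          for r in productive(rep) if len(r.cdr3_aa) >= 3]
                for s in scores:
                    rows.append({"sample_id": rep.sample_id, "cdr3_aa": s.cdr3_aa,
                                 "score": s.score, "positive": s.positive})
                if scores:
                    summ = summarize_immunogenicity(scores, rep.sample_id)
                    summary_rows[rep.sample_id].update(
                        positive_scoring=summ.positive_count,
                        percent_immunogenic=summ.percent_positive)
            pd.DataFrame(rows).to_csv(out / "immunogenicity.tsv", sep="\t",
                                      index=False)
            manifest["stages"]["immunogenicity"] = "ok"

        if "shared" in config.stages:
            stage = "shared"
            report = shared_clones(cohort)
            report.to_frame(cohort).to_csv(out / "shared_clones.tsv", sep="\t",
                                           index=False)
            equal_len = [seq for seq, _ in report.entries]
            if len(equal_len) >= 2 and len({len(s) for s in equal_len}) == 1:
                with open(out / "shared_alignment.txt", "w") as fh:
                    for seq, samples in report.entries:
                        fh.write(f"{'_'.join(sorted(samples)):<20}{seq}\n")
                    fh.write(" " * 20 + conservation_string(equal_len) + "\n")
            manifest["stages"]["shared"] = "ok"

        if "compare" in config.stages:
            stage = "compare"
            sample = "(all)"
            compare_clone_frequencies(cohort).to_frame().to_csv(
                out / "dunns_test.tsv", sep="\t", index=False)
            manifest["stages"]["compare"] = "ok"

        stage = "summary"
        pd.DataFrame(list(summary_rows.values())).to_csv(
            out / "summary.tsv", sep="\t", index=False)
        manifest["complete"] = True
    except Exception as exc:  # keep partial outputs, record the failure
        manifest["failed_stage"] = stage
        manifest["failed_sample"] = sample
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
        raise StageError(stage, sample, exc) from exc

    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
    return out


def _length_figure(cohort: Cohort, scale: str, path: Path) -> None:
    groups: dict[str, list] = {}
    for rep in cohort.repertoires:
        groups.setdefault(rep.group.value, []).append(rep)
    fig, axes = plt.subplots(1, max(len(groups), 1),
                             figsize=(5 * max(len(groups), 1), 3.5),
                             squeeze=False)
    for ax, (gname, reps) in zip(axes[0], groups.items()):
        all_lengths = sorted({L for rep in reps
                              for L in length_distribution(rep, scale).lengths})
        width = 0.8 / max(len(reps), 1)
        for i, rep in enumerate(reps):
            dist = length_distribution(rep, scale)
            freq = dict(zip(dist.lengths, dist.frequencies))
            xs = [j + i * width for j in range(len(all_lengths))]
            ax.bar(xs, [100 * freq.get(L, 0) for L in all_lengths],
                   width=width, label=rep.sample_id)
        ax.set_xticks(range(len(all_lengths)))
        ax.set_xticklabels(all_lengths, rotation=90, fontsize=6)
        ax.set_xlabel(f"CDR3 length ({scale})")
        ax.set_ylabel("sum productive frequency (%)")
        ax.set_title(gname)
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _clonality_figure(df: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    colors = {"ARDS": "#c44", "non_ARDS": "#48a", "unlabeled": "#999"}
    ax.bar(df["sample_id"], df["clonality"],
           color=[colors.get(g, "#999") for g in df["group"]])
    ax.set_ylabel("Simpson clonality")
    ax.set_xlabel("sample")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
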