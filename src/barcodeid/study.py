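"""End-to-end feasibility study: one configuration in, a report bundle out.

``run_study`` reproduces the full analysis arc on one dataset (read from
FASTA or simulated from a preset): distance summaries, the rooted NJ
tree, identification reports under the requested criteria for each
dataset variant (full / singletons stripped / named taxa stripped /
both), a threshold sweep with the ad hoc threshold regression, and the
problem-taxon flag table — all written to an output directory together
with a manifest (seed, config hash, versions) from which the bundle is
regenerable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .distances import distance_matrix, summarize_distances
from .identify import CRITERIA, evaluate_dataset
from .njtree import bootstrap_supports, build_nj, root_with_outgroup, write_newick
from .seqio import BarcodeDataset, read_labeled_fasta, write_labeled_fasta, write_report
from .simdata import preset, simulate_dataset
from .thresholds import (
    ad_hoc_threshold,
    default_sweep_grid,
    flag_problem_taxa,
    intraspecific_percentile_threshold,
    strip_dataset,
    threshold_sweep,
)

__all__ = ["StudyConfig", "StudyError", "run_study"]


class StudyError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class StudyConfig:
    """One fully specified study run. Exactly one of ``input_fasta`` and
    ``simulate_preset`` must be set."""

    output_dir: str
    input_fasta: str | None = None
    simulate_preset: str | None = None
    seed: int = 0
    criteria: tuple[str, ...] = CRITERIA
    threshold_mode: str = "percentile"  # percentile | fixed
    percentile: float = 95.0
    fixed_threshold: float | None = None
    run_sweep: bool = True
    sweep_upper: float = 0.15
    sweep_steps: int = 30
    max_rel_error: float = 0.05
    strip_singletons: bool = False
    drop_taxa: tuple[str, ...] = ()
    bootstrap_replicates: int = 0
    outgroup_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.input_fasta is None) == (self.simulate_preset is None):
            raise ValueError(
                "exactly one of input_fasta and simulate_preset must be set"
            )
        if self.threshold_mode not in ("percentile", "fixed"):
            raise ValueError("threshold_mode must be 'percentile' or 'fixed'")
        if self.threshold_mode == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold mode needs fixed_threshold")
        unknown = set(self.criteria) - set(CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_dataset(config: StudyConfig) -> BarcodeDataset:
    if config.input_fasta is not None:
        return read_labeled_fasta(
            config.input_fasta, outgroup_ids=config.outgroup_ids
        )
    truth = simulate_dataset(preset(config.simulate_preset, seed=config.seed))
    return truth.dataset


def _variants(config: StudyConfig, dataset: BarcodeDataset):
    yield "full", dataset
    if config.strip_singletons:
        yield "no_singletons", strip_dataset(dataset, drop_singletons=True).dataset
    if config.drop_taxa:
        yield "no_dropped_taxa", strip_dataset(
            dataset, drop_taxa=config.drop_taxa
        ).dataset
    if config.strip_singletons and config.drop_taxa:
        yield "stripped", strip_dataset(
            dataset, drop_singletons=True, drop_taxa=config.drop_taxa
        ).dataset


def run_study(config: StudyConfig) -> dict[str, object]:
    """Run the study; returns a manifest of artifacts and key numbers.

    On a stage failure, partial outputs are retained next to a ``FAILED``
    marker naming the stage, and :class:`StudyError` is raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "artifacts": [],
        "numbers": {},
    }
    artifacts: list[str] = manifest["artifacts"]  # type: ignore[assignment]
    numbers: dict[str, object] = manifest["numbers"]  # type: ignore[assignment]

    stage = "load"
    try:
        dataset = _load_dataset(config)
        if config.simulate_preset is not None:
            write_labeled_fasta(dataset, out / "dataset.fasta")
            artifacts.append("dataset.fasta")

        needs_tree = bool({"NJT", "NJT_M"} & set(config.criteria))
        for name, ds in _variants(config, dataset):
            stage = f"distances[{name}]"
            m = distance_matrix(ds)
            summary = summarize_distances(m, ds)
            (out / f"distance_summary_{name}.json").write_text(
                json.dumps(dataclasses.asdict(summary), indent=2) + "\n"
            )
            artifacts.append(f"distance_summary_{name}.json")

            stage = f"threshold[{name}]"
            if config.threshold_mode == "fixed":
                threshold = float(config.fixed_threshold)
            else:
                threshold = intraspecific_percentile_threshold(
                    m, ds, config.percentile
                )
            numbers[f"threshold_{name}"] = threshold

            tree = None
            if needs_tree:
                stage = f"tree[{name}]"
                tree = build_nj(m)
                if ds.outgroup_ids:
                    tree = root_with_outgroup(tree, next(iter(ds.outgroup_ids)))
                if name == "full" and config.bootstrap_replicates > 0:
                    tree = bootstrap_supports(
                        ds,
                        n_replicates=config.bootstrap_replicates,
                        seed=config.seed,
                        tree=tree,
                    )
                write_newick(tree, out / f"tree_{name}.nwk")
                artifacts.append(f"tree_{name}.nwk")

            stage = f"identify[{name}]"
            rows = []
            for criterion in config.criteria:
                report = evaluate_dataset(
                    ds, criterion, m=m, tree=tree, threshold=threshold
                )
                rows.append(report.summary_row())
                write_report(
                    report.verdict_rows(ds),
                    out / f"verdicts_{criterion}_{name}.tsv",
                )
                artifacts.append(f"verdicts_{criterion}_{name}.tsv")
                numbers[f"{criterion}_{name}_correct_pct"] = report.percentages[
                    "correct"
                ]
            write_report(rows, out / f"identification_{name}.tsv")
            artifacts.append(f"identification_{name}.tsv")

            if config.run_sweep:
                stage = f"sweep[{name}]"
                sweep = threshold_sweep(
                    ds,
                    m,
                    default_sweep_grid(config.sweep_upper, 0.0, config.sweep_steps),
                )
                write_report(sweep.to_rows(), out / f"sweep_{name}.tsv")
                artifacts.append(f"sweep_{name}.tsv")
                adhoc = ad_hoc_threshold(sweep, config.max_rel_error)
                (out / f"adhoc_threshold_{name}.json").write_text(
                    json.dumps(adhoc.to_dict(), indent=2) + "\n"
                )
                artifacts.append(f"adhoc_threshold_{name}.json")
                numbers[f"adhoc_estimate_{name}"] = adhoc.estimate
                numbers[f"adhoc_reliable_{name}"] = adhoc.reliable

            if name == "full":
                stage = "flags"
                reports = [
                    evaluate_dataset(
                        ds, c, m=m, tree=tree, threshold=threshold
                    )
                    for c in config.criteria
                ]
                flags = flag_problem_taxa(reports, ds, m=m)
                write_report(
                    [
                        {
                            "rank": f.rank,
                            "name": f.name,
                            "fraction_not_correct": f.fraction_not_correct,
                            "n_zero_allospecific": f.n_zero_allospecific,
                            "flagged": f.flagged,
                            "reasons": "; ".join(f.reasons),
                        }
                        for f in flags
                    ],
                    out / "flags.tsv",
                )
                artifacts.append("flags.tsv")
                numbers["n_flagged_taxa"] = sum(1 for f in flags if f.flagged)
    except Exception as err:  # noqa: BLE001 - named-stage abort contract
        (out / "FAILED").write_text(f"stage {stage} failed: {err}\n")
        raise StudyError(stage, err) from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
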