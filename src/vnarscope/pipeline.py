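"""End-to-end pipeline: filter -> annotate -> statistics -> (discovery).

One :class:`PipelineConfig` drives the whole run and one machine-readable
``summary.json`` is the authoritative output; TSV/FASTA/Newick artifacts are
written next to it.  Runs are deterministic for fixed inputs and config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import io as vio
from .annotation import NumberingScheme, DEFAULT_SCHEME
from .discovery import DiscoveryParams, run_discovery
from .filtering import AnchorConfig, filter_full_length
from .repertoire import (
    RepertoireDataset,
    abundance_fractions,
    collapse_unique,
    cysteine_distribution,
    dataset_overlap,
    length_distribution,
)

logger = logging.getLogger("vnarscope")


class PipelineError(RuntimeError):
    """A stage failure with a distinct, user-facing message."""


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    reads: str
    anchors: AnchorConfig
    out_dir: str
    library: str = "target"
    control_reads: Optional[str] = None
    control_library: str = "control"
    scheme: NumberingScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    discovery: Optional[DiscoveryParams] = None
    abundance_thresholds: Sequence[int] = (10,)
    log_level: str = "INFO"
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.reads).exists():
            raise PipelineError(f"reads file not found: {self.reads}")
        if self.control_reads is not None and not Path(self.control_reads).exists():
            raise PipelineError(f"control reads file not found: {self.control_reads}")
        if self.control_reads is not None and self.discovery is None:
            raise PipelineError("discovery parameters required when a control library is given")
        if any(t < 1 for t in self.abundance_thresholds):
            raise PipelineError("abundance thresholds must be >= 1")


def _process_library(
    config: PipelineConfig, reads_path: str, library: str, out: Path
) -> RepertoireDataset:
    logger.info("filtering %s (%s)", library, reads_path)
    try:
        reads = vio.read_reads(reads_path)
        result = filter_full_length(reads, config.anchors)
    except (ValueError, OSError) as exc:
        raise PipelineError(f"failed to filter {reads_path}: {exc}") from exc
    logger.info(
        "%s: %d reads in, %d full-length out",
        library,
        result.stats.total_reads,
        result.stats.stop_free_full_length,
    )
    vio.write_rejections_tsv(result.rejections, out / f"{library}.rejections.tsv")
    with open(out / f"{library}.filter_stats.json", "w") as fh:
        json.dump(result.stats.as_dict(), fh, indent=2)

    ds = collapse_unique(result.sequences, library, filter_stats=result.stats)
    rejected = ds.annotate(config.scheme)
    if rejected:
        logger.info("%s: unannotated clones by reason: %s", library, rejected)
    ds.to_tsv(out / f"{library}.clones.tsv")
    vio.write_fasta(
        ((c.clone_id, c.aa_sequence) for c in ds.clones),
        out / f"{library}.clones.fasta",
    )
    return ds


def _library_summary(config: PipelineConfig, ds: RepertoireDataset) -> dict:
    summary: dict = {
        "library": ds.library,
        "filter_stats": ds.filter_stats.as_dict() if ds.filter_stats else None,
        "n_unique_clones": len(ds),
        "unannotated": ds.unannotated,
    }
    if ds.clones:
        fractions = abundance_fractions(ds, config.abundance_thresholds)
        summary["singleton_fraction"] = fractions.singleton_fraction
        summary["fraction_below_threshold"] = {
            str(t): v for t, v in fractions.below.items()
        }
    annotated = ds.annotated_clones()
    if annotated:
        subtype_counts: dict[str, int] = {}
        for c in annotated:
            subtype_counts[c.subtype] = subtype_counts.get(c.subtype, 0) + 1
        summary["subtype_distribution"] = dict(sorted(subtype_counts.items()))
        summary["cdr3_length"] = length_distribution(ds, "cdr3").as_dict()
        summary["cysteines_full"] = {
            str(k): v for k, v in sorted(cysteine_distribution(ds, "full").items())
        }
        summary["cysteines_cdr3"] = {
            str(k): v for k, v in sorted(cysteine_distribution(ds, "cdr3").items())
        }
    return summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and write the report bundle.

    Returns the summary dict (also written to ``<out_dir>/summary.json``).
    Raises :class:`PipelineError` with a distinct message on any stage failure.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    target = _process_library(config, config.reads, config.library, out)
    summary: dict = {
        "seed": config.seed,
        "libraries": {config.library: _library_summary(config, target)},
    }

    if config.control_reads is not None:
        control = _process_library(
            config, config.control_reads, config.control_library, out
        )
        summary["libraries"][config.control_library] = _library_summary(
            config, control
        )
        overlap = dataset_overlap(target, control)
        summary["overlap"] = {
            "unique_to_target": overlap.unique_to_a,
            "shared": overlap.shared,
            "unique_to_control": overlap.unique_to_b,
            "shared_fraction": overlap.shared_fraction,
        }
        logger.info("running discovery at CDR3 length %d", config.discovery.cdr3_length)
        discovery = run_discovery(target, control, config.discovery)
        with open(out / "cdr3_tree.nwk", "w") as fh:
            fh.write(discovery.newick())
        with open(out / "clades.tsv", "w") as fh:
            fh.write("clade_id\tsize\tsource_purity\trepresentative\tcount\tcdr3\n")
            for clade in discovery.clades:
                rep = clade.representative
                fh.write(
                    f"{clade.clade_id}\t{clade.size}\t{clade.source_purity:.4f}\t"
                    f"{rep.clone_id}\t{rep.count}\t{rep.cdr3}\n"
                )
        summary["discovery"] = {
            "params": {
                "cdr3_length": config.discovery.cdr3_length,
                "identity_threshold": config.discovery.identity_threshold,
                "top_k": config.discovery.top_k,
                "min_clade_size": config.discovery.min_clade_size,
                "purity": config.discovery.purity,
            },
            "n_clades": len(discovery.clades),
            "clades": [
                {
                    "clade_id": c.clade_id,
                    "size": c.size,
                    "source_purity": c.source_purity,
                    "representative": c.representative.clone_id,
                    "representative_count": c.representative.count,
                    "representative_cdr3": c.representative.cdr3,
                }
                for c in discovery.clades
            ],
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("summary written to %s", out / "summary.json")
    return summary
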