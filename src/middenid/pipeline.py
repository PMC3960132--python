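"""End-to-end orchestration of the multi-evidence identification.

Stages run in a fixed order — morphometrics, replicate consensus,
haplotype comparison, parsimony, calibration — each producing a report
section.  Evidence streams are independent: a pellets-only run marks
the DNA sections skipped.  Every stage logs a digest of its inputs and
the seed in use, so reported numbers are auditable, and the whole run
is deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any

from . import __version__
from .calibration import CalibrationCurve, RadiocarbonDate, calibrate_range
from .compare import ReferenceHaplotype, difference_matrix, match_exact, star_align
from .config import PipelineConfig
from .consensus import ConsensusSequence, ReplicateRead, consensus_from_reads
from .morphometrics import PelletMeasurement, classify_sample
from .parsimony import encode_states, heuristic_search

log = logging.getLogger("middenid.pipeline")

SKIPPED = "skipped"

#: label given to the ancient consensus in alignments and trees
QUERY_LABEL = "ancient_sample"


@dataclass
class PipelineInputs:
    pellets: list[PelletMeasurement] | None = None
    reads: dict[str, list[ReplicateRead]] | None = None   # fragment -> replicates
    panel: list[ReferenceHaplotype] | None = None
    dates: list[RadiocarbonDate] | None = None
    curve: CalibrationCurve | None = None


@dataclass
class IdentificationReport:
    morphometrics: Any = SKIPPED
    consensus: dict[str, ConsensusSequence] | str = SKIPPED
    comparison: dict[str, Any] | str = SKIPPED
    parsimony: Any = SKIPPED
    calibration: Any = SKIPPED
    provenance: dict[str, Any] = field(default_factory=dict)

    def summary(self) -> dict[str, Any]:
        """JSON-serializable digest of every section."""
        out: dict[str, Any] = {"provenance": self.provenance}
        if self.morphometrics == SKIPPED:
            out["morphometrics"] = SKIPPED
        else:
            m = self.morphometrics
            out["morphometrics"] = {
                "n": m.n,
                "modal_class": m.modal_class.value,
                "counts": {k.value: v for k, v in m.counts.items()},
                "mean_length_mm": round(m.mean_length_mm, 3),
                "mean_width_mm": round(m.mean_width_mm, 3),
            }
        if self.consensus == SKIPPED:
            out["consensus"] = SKIPPED
        else:
            out["consensus"] = {
                frag: {"bases": c.bases, "n_forward": c.n_forward,
                       "n_reverse": c.n_reverse}
                for frag, c in self.consensus.items()
            }
        if self.comparison == SKIPPED:
            out["comparison"] = SKIPPED
        else:
            out["comparison"] = {
                "exact_matches": self.comparison["exact_matches"],
                "differences": {
                    frag: {r.ref_id: r.total_differences for r in reports}
                    for frag, reports in self.comparison["differences"].items()
                },
            }
        if self.parsimony == SKIPPED:
            out["parsimony"] = SKIPPED
        else:
            out["parsimony"] = {
                "best_score": self.parsimony.best_score,
                "n_optimal_trees": len(self.parsimony.optimal_trees),
                "consensus_newick": self.parsimony.consensus.newick(
                    with_support=True
                ),
            }
        if self.calibration == SKIPPED:
            out["calibration"] = SKIPPED
        else:
            c = self.calibration
            out["calibration"] = {
                "span_cal_bp": [round(c.span[0], 1), round(c.span[1], 1)],
                "medians_cal_bp": [round(m, 1) for m in c.medians],
            }
        return out

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.summary(), indent=2, **kwargs)


def _digest(obj: Any) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(
    inputs: PipelineInputs, config: PipelineConfig | None = None
) -> IdentificationReport:
    """Run every stage for which input evidence is present."""
    cfg = (config or PipelineConfig()).validate()
    if inputs.pellets is None and inputs.reads is None:
        raise ValueError("at least one evidence stream (pellets or reads) required")

    report = IdentificationReport()
    report.provenance = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "version": __version__,
    }

    if inputs.pellets:
        log.info("morphometrics: %d pellets, digest %s",
                 len(inputs.pellets), _digest(inputs.pellets))
        report.morphometrics = _stage("morphometrics")(classify_sample)(
            inputs.pellets, cfg
        )

    consensus: dict[str, ConsensusSequence] = {}
    if inputs.reads:
        for frag in sorted(inputs.reads):
            reads = inputs.reads[frag]
            log.info("consensus[%s]: %d replicates, digest %s",
                     frag, len(reads), _digest(reads))
            consensus[frag] = _stage("consensus")(consensus_from_reads)(reads, cfg)
        report.consensus = consensus

    if consensus and inputs.panel:
        scores = (cfg.match_score, cfg.mismatch_score, cfg.gap_score)

        @_stage("comparison")
        def _compare() -> dict[str, Any]:
            diffs = {}
            per_frag_matches = {}
            for frag, cons in consensus.items():
                diffs[frag] = difference_matrix(
                    cons.bases, inputs.panel, query_id=frag, scores=scores
                )
                per_frag_matches[frag] = match_exact(
                    cons.bases, inputs.panel, scores=scores
                )
            exact = sorted(
                set.intersection(*map(set, per_frag_matches.values()))
            ) if per_frag_matches else []
            return {
                "differences": diffs,
                "exact_matches": exact,
                "per_fragment_matches": per_frag_matches,
            }

        report.comparison = _compare()

        @_stage("parsimony")
        def _parsimony():
            query = "".join(c.bases for _, c in sorted(consensus.items()))
            records = [(QUERY_LABEL, query)] + [
                (ref.accession, ref.bases) for ref in inputs.panel
            ]
            aligned = star_align(records, scores=scores)
            matrix = encode_states(aligned)
            result = heuristic_search(
                matrix, n_starts=cfg.n_starts, swap=cfg.swap, seed=cfg.seed
            )
            if cfg.outgroup:
                result.consensus = (
                    result.consensus.root_with_outgroup(cfg.outgroup)
                )
            return result

        log.info("parsimony: %d panel refs, %d starts, seed %d",
                 len(inputs.panel), cfg.n_starts, cfg.seed)
        report.parsimony = _parsimony()

    if inputs.dates and inputs.curve:
        log.info("calibration: %d dates, digest %s",
                 len(inputs.dates), _digest(inputs.dates))
        report.calibration = _stage("calibration")(calibrate_range)(
            inputs.dates, inputs.curve, cfg.calib_step
        )

    return report
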