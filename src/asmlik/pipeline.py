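"""End-to-end orchestration: learn parameters, rescue, total likelihood."""

from __future__ import annotations

from dataclasses import dataclass

from .error_model import ErrorModel, learn_error_model
from .fragment_model import FragmentLengthDistribution, StartSiteModel, learn_fragment_lengths
from .io_formats import AssemblyIndex, ReadPair, RoutedReadSet
from .likelihood import LikelihoodReport, per_read_probability, total_log_likelihood
from .rescue import RescueResult, SWScores, rescue_sample


@dataclass
class PipelineResult:
    report: LikelihoodReport
    fragment_model: FragmentLengthDistribution
    error_model: ErrorModel
    rescue: RescueResult | None


def evaluate_assembly(
    assembly: AssemblyIndex,
    routed: RoutedReadSet,
    reads_by_id: dict[str, ReadPair] | None = None,
    *,
    fragment_model: FragmentLengthDistribution | None = None,
    error_model: ErrorModel | None = None,
    fragment_pseudocount: float = 1.0,
    error_pseudocount: float = 1.0,
    rescue_sample_size: int = 500,
    seed: int = 0,
    threads: int = 1,
    sw_scores: SWScores = SWScores(),
    orientation: str = "FR",
    rescue_result: RescueResult | None = None,
) -> PipelineResult:
    """Learn p_F and the error model from uniquely mapped pairs (unless
    supplied), rescue whatever the mapper could not place, and return the
    total log likelihood report.

    Passing ``fragment_model``/``error_model`` explicitly turns this into
    true-parameter evaluation of the same routed read set; passing a
    pre-computed ``rescue_result`` (the align stage's output) skips the
    rescue alignments.
    """
    if fragment_model is None or error_model is None:
        unique = routed.unique_mappings()
        if fragment_model is None:
            fragment_model = learn_fragment_lengths(unique, fragment_pseudocount)
        if error_model is None:
            error_model = learn_error_model(unique, assembly, pseudocount=error_pseudocount)
    p_S = StartSiteModel(assembly)

    precomputed = {}
    needs_rescue = []
    for pid in sorted(routed.both_mapped):
        prl = per_read_probability(routed.both_mapped[pid], fragment_model, p_S, error_model)
        precomputed[pid] = prl
        if prl is None:
            needs_rescue.append(pid)
    pool_ids = routed.non_mapped_ids + needs_rescue

    if pool_ids and rescue_result is None:
        if reads_by_id is None:
            raise ValueError(
                f"{len(pool_ids)} pairs need rescue but no read sequences were supplied"
            )
        pool = [reads_by_id[pid] for pid in pool_ids if pid in reads_by_id]
        if len(pool) != len(pool_ids):
            missing = len(pool_ids) - len(pool)
            raise ValueError(f"{missing} rescue-pool pair ids missing from the read set")
        rescue_result = rescue_sample(
            pool,
            assembly,
            fragment_model,
            p_S,
            error_model,
            sample_size=rescue_sample_size,
            seed=seed,
            threads=threads,
            scores=sw_scores,
            orientation=orientation,
        )
    report = total_log_likelihood(
        routed, fragment_model, p_S, error_model, rescue_result, precomputed=precomputed
    )
    report.parameters.update(
        {
            "seed": seed,
            "rescue_sample_size": rescue_sample_size,
            "orientation": orientation,
        }
    )
    return PipelineResult(report, fragment_model, error_model, rescue_result)
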