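"""Likelihood engine: combine fragment, start-site and error models.

The probability of one read pair is a sum over its candidate placements
(mappings) of p_F(fragment length) * p_S(start site) * 1/2 (strand) *
p_E(observed ends | placed reference).  The assembly's total log likelihood
is the sum of per-pair log probabilities over all pairs, with pairs the
mapper could not place handled by the rescue module.  All arithmetic is in
natural-log space with log-sum-exp aggregation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, TYPE_CHECKING

from scipy.special import logsumexp

from .error_model import ErrorModel, p_error_pair
from .fragment_model import FragmentLengthDistribution, StartSiteModel
from .io_formats import MappingRecord, RoutedReadSet

if TYPE_CHECKING:  # pragma: no cover
    from .rescue import RescueResult

LOG_HALF = math.log(0.5)
_NEG_INF = float("-inf")


@dataclass(frozen=True)
class PerReadLikelihood:
    pair_id: str
    log_probability: float
    n_mappings: int
    category: str  # "mapped" | "rescued" | "cross_scaffold" | "unmapped_imputed"


@dataclass
class LikelihoodReport:
    """Total log likelihood of an assembly with per-category breakdown."""

    total_log_likelihood: float
    n_reads: int
    category_counts: dict[str, int] = field(default_factory=dict)
    category_subtotals: dict[str, float] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_log_likelihood": self.total_log_likelihood,
            "n_reads": self.n_reads,
            "category_counts": self.category_counts,
            "category_subtotals": self.category_subtotals,
            "parameters": self.parameters,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_text(self) -> str:
        lines = [
            f"total log likelihood (natural log): {self.total_log_likelihood!r}"
            f" ({self.total_log_likelihood:.6e})",
            f"reads: {self.n_reads}",
        ]
        for cat in sorted(self.category_counts):
            sub = self.category_subtotals.get(cat)
            subtxt = f" subtotal {sub:.6e}" if sub is not None else ""
            lines.append(f"  {cat}: {self.category_counts[cat]}{subtxt}")
        return "\n".join(lines)


def mapping_log_term(
    record: MappingRecord,
    p_F: FragmentLengthDistribution,
    p_S: StartSiteModel,
    p_E: ErrorModel,
) -> float:
    """log[ p_F(l) * p_S(s) * 1/2 * p_E ] for one mapping; -inf if any
    factor is zero (e.g. fragment length outside the learned support)."""
    lf = p_F.log_pmf(record.fragment_length)
    if lf == _NEG_INF:
        return _NEG_INF
    ls = p_S.log_p_start(record.fragment_length)
    if ls == _NEG_INF:
        return _NEG_INF
    return lf + ls + LOG_HALF + p_error_pair(p_E, record)


def per_read_probability(
    mappings: Iterable[MappingRecord],
    p_F: FragmentLengthDistribution,
    p_S: StartSiteModel,
    p_E: ErrorModel,
) -> PerReadLikelihood | None:
    """Log probability of one pair summed over its mappings (log-sum-exp).

    Mappings contributing exactly zero probability are skipped; if every
    mapping vanishes the function returns None and the caller should route
    the pair through rescue instead.
    """
    mappings = list(mappings)
    if not mappings:
        raise ValueError("per_read_probability requires at least one mapping")
    terms = []
    for rec in mappings:
        t = mapping_log_term(rec, p_F, p_S, p_E)
        if t != _NEG_INF:
            terms.append(t)
    if not terms:
        return None
    return PerReadLikelihood(
        pair_id=mappings[0].pair_id,
        log_probability=float(logsumexp(terms)),
        n_mappings=len(mappings),
        category="mapped",
    )


def total_log_likelihood(
    routed: RoutedReadSet,
    p_F: FragmentLengthDistribution,
    p_S: StartSiteModel,
    p_E: ErrorModel,
    rescue_result: "RescueResult | None" = None,
    precomputed: dict[str, PerReadLikelihood | None] | None = None,
) -> LikelihoodReport:
    """Total log likelihood over all routed pairs.

    Pairs in ``both_mapped`` are scored by :func:`per_read_probability`.
    All other pairs (one end mapped, neither mapped, ends on different
    scaffolds) - and any mapped pair whose every mapping vanishes under the
    learned models - take their value from ``rescue_result``: their own
    sampled value if they were in the rescue sample, otherwise the imputed
    (geometric-mean) value.
    """
    mapped_values: list[float] = []
    needs_rescue: list[str] = []
    for pair_id in sorted(routed.both_mapped):
        if precomputed is not None and pair_id in precomputed:
            prl = precomputed[pair_id]
        else:
            prl = per_read_probability(routed.both_mapped[pair_id], p_F, p_S, p_E)
        if prl is None:
            needs_rescue.append(pair_id)
        else:
            mapped_values.append(prl.log_probability)

    counts = {
        "mapped": len(mapped_values),
        "one_end_mapped": len(routed.one_end_mapped),
        "neither_mapped": len(routed.neither_mapped),
        "cross_scaffold": len(routed.cross_scaffold),
        "mapped_but_zero_probability": len(needs_rescue),
    }
    subtotal_mapped = math.fsum(mapped_values)
    other_ids = routed.non_mapped_ids + needs_rescue

    subtotal_rescued = 0.0
    subtotal_imputed = 0.0
    n_sampled = 0
    if other_ids:
        if rescue_result is None:
            raise ValueError(
                f"{len(other_ids)} pairs have no mapping-based probability and no "
                "rescue result was supplied; run the align (rescue) stage first"
            )
        sampled = rescue_result.per_pair_log_probability
        for pid in other_ids:
            if pid in sampled:
                subtotal_rescued += sampled[pid]
                n_sampled += 1
            else:
                subtotal_imputed += rescue_result.imputed_log_probability
        if mapped_values and rescue_result.sampled_pair_ids:
            mean_mapped = subtotal_mapped / len(mapped_values)
            if rescue_result.imputed_log_probability > mean_mapped:
                warnings.warn(
                    "imputed unmapped-read log probability exceeds the mean mapped "
                    "log probability; this is anomalous"
                )
    counts["rescued_sampled"] = n_sampled
    counts["unmapped_imputed"] = len(other_ids) - n_sampled

    total = subtotal_mapped + subtotal_rescued + subtotal_imputed
    if math.isnan(total) or total == _NEG_INF:
        raise ValueError("total log likelihood is not finite")
    return LikelihoodReport(
        total_log_likelihood=total,
        n_reads=routed.n_pairs,
        category_counts=counts,
        category_subtotals={
            "mapped": subtotal_mapped,
            "rescued_sampled": subtotal_rescued,
            "unmapped_imputed": subtotal_imputed,
        },
        parameters={
            "fragment_support": [p_F.support_min, p_F.support_max],
            "fragment_mean": p_F.mean(),
            "read_length": p_E.read_length,
            "assembly_total_length": p_S.assembly.total_length,
            "n_contigs": len(p_S.assembly),
        },
    )
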