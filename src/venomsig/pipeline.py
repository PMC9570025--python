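"""End-to-end analysis: from input tables to up/down-in-males calls."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .maturation import PrecursorRecord, mature_candidates, strip_signal
from .spectral_evidence import (
    GROUPS,
    ConsensusSignal,
    PeakList,
    consensus_signals,
    presence_table,
)
from .specificity import (
    ExpressionTriplet,
    HomologyHit,
    PSMRecord,
    SpecificityCall,
    build_report,
    call_specificity,
    classify_annotation,
    drop_redundant,
    expression_contrast,
    filter_psms,
)

__all__ = ["AnalysisResult", "run_analysis"]


@dataclass
class AnalysisResult:
    report: pd.DataFrame
    calls: list[SpecificityCall]
    consensus: dict[str, list[ConsensusSignal]]
    peptides: dict[str, list] = field(default_factory=dict)


def run_analysis(
    precursors: list[PrecursorRecord],
    peaklists: list[PeakList],
    expression: dict[str, ExpressionTriplet],
    psms: list[PSMRecord] | None = None,
    homology: dict[str, list[HomologyHit]] | None = None,
    config=None,
) -> AnalysisResult:
    """Run the full discovery pipeline.

    Steps: PSM quality filter and redundancy removal; maturation of each
    surviving precursor (annotated strategy, or AUTO); mass prediction;
    per-group MALDI consensus; presence matching; expression contrast;
    conjunction into the final call. Precursors removed by the quality
    filter appear in the report with call ``filtered``.
    """
    if config is None:
        from .io_formats import RunConfig

        config = RunConfig()
    homology = homology or {}

    surviving = {p.id for p in precursors}
    if psms is not None:
        good = filter_psms(
            psms, config.min_neg_log_p, config.min_coverage_pct
        )
        surviving &= {r.precursor_id for r in good}
        chains = {
            p.id: strip_signal(p) for p in precursors if p.id in surviving
        }
        surviving = set(drop_redundant(chains, good))

    peptides: dict[str, list] = {
        p.id: mature_candidates(
            p, trim_basic_residues=config.trim_basic_residues
        )
        for p in precursors
        if p.id in surviving
    }
    all_peptides = [pep for peps in peptides.values() for pep in peps]

    consensus = {
        group: consensus_signals(
            [pl for pl in peaklists if pl.group == group],
            config.cluster_tolerance_da,
            config.min_occurrence_fraction,
        )
        for group in GROUPS
    }
    presence = presence_table(all_peptides, consensus, config.mass_tolerance_da)

    calls: list[SpecificityCall] = []
    classes: dict[str, str] = {}
    for p in precursors:
        if p.id not in surviving:
            calls.append(
                SpecificityCall(
                    precursor_id=p.id,
                    call="filtered",
                    maldi_presence=(False, False, False),
                    expression_direction="flat",
                    gland_enriched=False,
                )
            )
            continue
        tri = expression.get(
            p.id, ExpressionTriplet(0.0, 0.0, 0.0)
        )
        direction, gland = expression_contrast(tri, config.min_fold_change)
        pattern = tuple(presence.get((p.id, g), False) for g in GROUPS)
        calls.append(call_specificity(p.id, pattern, direction, gland))
        if p.id in homology:
            classes[p.id] = classify_annotation(homology[p.id])
        else:
            classes[p.id] = p.class_label

    report = build_report(calls, peptides, expression, classes)
    return AnalysisResult(
        report=report, calls=calls, consensus=consensus, peptides=peptides
    )
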