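"""Single-study analysis pipeline: trace, classify, aggregate, energetics, QC."""

from __future__ import annotations

from dataclasses import dataclass

from .components import (
    ClassificationRules,
    ComponentResult,
    QCReport,
    classify_pathlines,
    component_volumes,
    qc_conservation,
)
from .energetics import KECurves, ke_ratios_at_ed, ke_timecurves
from .field_io import FlowStudy
from .tracing import IntegratorOptions, TracedSet, trace_cycle


@dataclass
class StudyAnalysis:
    """Everything the pipeline derives from one flow study."""

    traced: TracedSet
    labels: object
    result: ComponentResult
    ke: KECurves
    ke_ratios: dict
    qc: QCReport


def analyze_study(
    study: FlowStudy,
    substeps: int = 10,
    crossing_rule: str = "net",
    qc_threshold: float = 0.10,
) -> StudyAnalysis:
    """Run the full per-subject analysis.

    Traces one pathline per ED voxel (backward through diastole, forward
    through systole), classifies the four flow components, aggregates volumes
    and LVEDV ratios, computes the KE curves and ED KE ratios, and applies
    the inflow/outflow conservation QC.
    """
    traced = trace_cycle(study, IntegratorOptions(substeps=substeps))
    labels = classify_pathlines(traced, rules=ClassificationRules(crossing_rule=crossing_rule))
    result = component_volumes(labels, traced)
    ke = ke_timecurves(traced, labels)
    ratios = ke_ratios_at_ed(ke)
    qc = qc_conservation(result, threshold=qc_threshold)
    return StudyAnalysis(traced=traced, labels=labels, result=result, ke=ke,
                         ke_ratios=ratios, qc=qc)
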