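"""End-to-end convenience layer: counts -> calls -> annotations -> origins.

Used by the examples, the CLI and the simulation-recovery tests; each step is
a thin composition of the module-level operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotate import VariantAnnotation, annotate_variant
from .caller import PipelineConfig, call_frame
from .origins import OriginCall, PresenceMatrix, build_presence, classify_all
from .reference import MitoGenome
from .simulate import SimulatedCohort


@dataclass
class PipelineResult:
    calls: pd.DataFrame
    matrices: dict[str, PresenceMatrix]
    origin_calls: list[OriginCall]
    annotations: dict[tuple[int, str, str], VariantAnnotation]


@dataclass(frozen=True)
class _Var:
    position: int
    ref: str
    alt: str


def run_pipeline(
    cohort: SimulatedCohort, config: PipelineConfig | None = None
) -> PipelineResult:
    """Call every sample of a cohort, classify origins, annotate variants."""
    config = config or PipelineConfig()
    frames = [
        call_frame(df, cohort.genome, config) for df in cohort.counts.values()
    ]
    calls = (
        pd.concat([f for f in frames if not f.empty], ignore_index=True)
        if any(not f.empty for f in frames)
        else pd.DataFrame(
            columns=["sample_id", "pos", "ref", "alt", "heteroplasmy", "coverage"]
        )
    )
    matrices = build_presence(calls, cohort.manifest)
    origin_calls = [o for pm in matrices.values() for o in classify_all(pm)]
    annotations: dict[tuple[int, str, str], VariantAnnotation] = {}
    for o in origin_calls:
        if o.key not in annotations:
            pos, ref, alt = o.key
            annotations[o.key] = annotate_variant(
                _Var(pos, ref, alt), cohort.genome
            )
    return PipelineResult(calls, matrices, origin_calls, annotations)


def label_recovery(
    origin_calls: list[OriginCall], truth
) -> tuple[int, int, float]:
    """(n_matched, n_truth_detected, recovery fraction) of origin labels.

    A truth record counts as detected when its (animal, variant) appears among
    the classified calls; recovery is the fraction of detected records whose
    inferred origin equals the generative label.
    """
    inferred = {(o.animal_id, o.key): o.origin for o in origin_calls}
    matched = detected = 0
    for t in truth:
        lab = inferred.get((t.animal_id, t.key))
        if lab is None:
            continue
        detected += 1
        if lab == t.origin:
            matched += 1
    frac = matched / detected if detected else float("nan")
    return matched, detected, frac
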