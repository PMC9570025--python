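"""Evidence filtering, annotation-based classification and male up/down calls.

The final verdict per precursor combines three evidence layers:

1. MALDI presence/absence — the primary criterion. ``up_in_males``
   requires the peptide's mass among the reproducible male consensus
   signals and its absence from both female and juvenile signals;
   ``down_in_males`` is the mirror pattern (females and juveniles share
   fingerprints, so absence in males must be consistent in both other
   groups).
2. Transcriptome support — the telson TPM of the favoured sex must exceed
   the other sex by a configurable fold (default 2).
3. Proteome quality — only precursors with a confident peptide-spectrum
   match (-10lgP > 30, coverage > 7%, both strict) and an annotated signal
   peptide enter the analysis at all.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PSMRecord",
    "ExpressionTriplet",
    "HomologyHit",
    "SpecificityCall",
    "filter_psms",
    "classify_annotation",
    "expression_contrast",
    "call_specificity",
    "drop_redundant",
    "build_report",
]

EXPERIMENT_TAGS = frozenset({"D-m", "D-f", "ND-m", "ND-f"})


@dataclass(frozen=True)
class PSMRecord:
    """Search-engine evidence for one precursor."""

    precursor_id: str
    neg_log_p: float
    coverage_pct: float
    has_signal_peptide: bool
    experiments: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.neg_log_p < 0:
            raise ValueError("-10lgP must be non-negative")
        if not 0 <= self.coverage_pct <= 100:
            raise ValueError("coverage must lie in [0, 100]")
        bad = self.experiments - EXPERIMENT_TAGS
        if bad:
            raise ValueError(f"unknown experiment tag(s) {sorted(bad)}")


@dataclass(frozen=True)
class ExpressionTriplet:
    """TPM in male telson, female telson and the gland-free control."""

    tpm_male_telson: float
    tpm_female_telson: float
    tpm_negative_control: float

    def __post_init__(self) -> None:
        if min(
            self.tpm_male_telson,
            self.tpm_female_telson,
            self.tpm_negative_control,
        ) < 0:
            raise ValueError("TPM values must be non-negative")


@dataclass(frozen=True)
class HomologyHit:
    database: str  # "metazoa" | "toxprot"
    description: str
    e_value: float

    def __post_init__(self) -> None:
        if self.database not in {"metazoa", "toxprot"}:
            raise ValueError(f"unknown database {self.database!r}")
        if self.e_value < 0:
            raise ValueError("E-value must be non-negative")


@dataclass(frozen=True)
class SpecificityCall:
    precursor_id: str
    call: str  # up_in_males | down_in_males | unspecific | filtered
    maldi_presence: tuple[bool, bool, bool]  # (male, female, juvenile)
    expression_direction: str  # male_up | female_up | flat
    gland_enriched: bool


def filter_psms(
    records: list[PSMRecord],
    min_neg_log_p: float = 30.0,
    min_coverage_pct: float = 7.0,
) -> list[PSMRecord]:
    """Retain confident PSMs: strict inequalities, signal peptide required."""
    return [
        r
        for r in records
        if r.neg_log_p > min_neg_log_p
        and r.coverage_pct > min_coverage_pct
        and r.has_signal_peptide
    ]


# keyword map from BLAST-hit descriptions to venom compound classes;
# checked in order, first match wins ("inhibitor" before the enzyme rule so
# that protease inhibitors are not mistaken for proteases)
_CLASS_RULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("neurotoxin", ("toxin", "channel", "la1", "aktx")),
    ("AMP", ("antimicrobial", "non-disulfide bridge")),
    ("protease inhibitor", ("inhibitor",)),
)
_ENZYME_RE = re.compile(r"\b\w+ase\b", re.IGNORECASE)

METAZOA_E_CUTOFF = 1e-5
# Tox-Prot searches run at a permissive E-value (0.1) but contribute to
# classification only below the strict cutoff
TOXPROT_CLASS_E_CUTOFF = 1e-5


def classify_annotation(hits: list[HomologyHit]) -> str:
    """Class label from the best accepted homology hit; no hit -> novel."""
    accepted = [
        h
        for h in hits
        if (h.database == "metazoa" and h.e_value < METAZOA_E_CUTOFF)
        or (h.database == "toxprot" and h.e_value < TOXPROT_CLASS_E_CUTOFF)
    ]
    if not accepted:
        return "novel"
    best = min(accepted, key=lambda h: h.e_value)
    desc = best.description.lower()
    for label, keywords in _CLASS_RULES:
        if any(k in desc for k in keywords):
            return label
    if _ENZYME_RE.search(desc):
        return "enzyme"
    return "other"


def expression_contrast(
    triplet: ExpressionTriplet, min_fold: float = 2.0
) -> tuple[str, bool]:
    """Fold-change direction between the sexes, plus gland enrichment.

    ``male_up`` iff male TPM exceeds ``min_fold`` times the female TPM
    (symmetrically for ``female_up``), else ``flat``. The precursor is
    gland-enriched when both telson TPMs exceed the gland-free control.
    """
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    m, f = triplet.tpm_male_telson, triplet.tpm_female_telson
    if m > min_fold * f:
        direction = "male_up"
    elif f > min_fold * m:
        direction = "female_up"
    else:
        direction = "flat"
    gland_enriched = min(m, f) > triplet.tpm_negative_control
    return direction, gland_enriched


def call_specificity(
    precursor_id: str,
    presence: tuple[bool, bool, bool],
    direction: str,
    gland_enriched: bool = False,
) -> SpecificityCall:
    """Combine MALDI presence pattern and expression direction.

    The MALDI pattern is primary and the transcriptome must agree:
    up_in_males needs (male present, female absent, juvenile absent) and
    male_up expression; down_in_males the mirror image; anything else is
    unspecific.
    """
    male, female, juvenile = presence
    if (male, female, juvenile) == (True, False, False) and direction == "male_up":
        call = "up_in_males"
    elif (male, female, juvenile) == (False, True, True) and direction == "female_up":
        call = "down_in_males"
    else:
        call = "unspecific"
    return SpecificityCall(
        precursor_id=precursor_id,
        call=call,
        maldi_presence=presence,
        expression_direction=direction,
        gland_enriched=gland_enriched,
    )


def drop_redundant(
    chains: dict[str, str], psms: list[PSMRecord]
) -> list[str]:
    """Collapse precursors with identical mature chains.

    Returns the retained precursor ids: one per distinct chain sequence,
    keeping the precursor with the highest-scoring PSM (ties broken by id
    for determinism).
    """
    best_score: dict[str, float] = {}
    for r in psms:
        best_score[r.precursor_id] = max(
            best_score.get(r.precursor_id, 0.0), r.neg_log_p
        )
    by_chain: dict[str, list[str]] = {}
    for pid, chain in chains.items():
        by_chain.setdefault(chain, []).append(pid)
    keep = []
    for members in by_chain.values():
        members.sort(key=lambda pid: (-best_score.get(pid, 0.0), pid))
        keep.append(members[0])
    return sorted(keep)


def build_report(
    calls: list[SpecificityCall],
    peptides_by_id: dict[str, list] | None = None,
    expression: dict[str, ExpressionTriplet] | None = None,
    classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per precursor: the machine-readable analogue of the
    published summary table."""
    peptides_by_id = peptides_by_id or {}
    expression = expression or {}
    classes = classes or {}
    rows = []
    for c in sorted(calls, key=lambda c: c.precursor_id):
        peps = peptides_by_id.get(c.precursor_id, [])
        tri = expression.get(c.precursor_id)
        rows.append(
            {
                "id": c.precursor_id,
                "class": classes.get(c.precursor_id, ""),
                "mature_peptides": ";".join(p.sequence for p in peps),
                "predicted_mh": ";".join(f"{p.predicted_mh:.2f}" for p in peps),
                "maldi_male": c.maldi_presence[0],
                "maldi_female": c.maldi_presence[1],
                "maldi_juvenile": c.maldi_presence[2],
                "tpm_male": tri.tpm_male_telson if tri else float("nan"),
                "tpm_female": tri.tpm_female_telson if tri else float("nan"),
                "tpm_control": tri.tpm_negative_control if tri else float("nan"),
                "expression_direction": c.expression_direction,
                "gland_enriched": c.gland_enriched,
                "call": c.call,
            }
        )
    columns = [
        "id", "class", "mature_peptides", "predicted_mh",
        "maldi_male", "maldi_female", "maldi_juvenile",
        "tpm_male", "tpm_female", "tpm_control",
        "expression_direction", "gland_enriched", "call",
    ]
    return pd.DataFrame(rows, columns=columns)
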