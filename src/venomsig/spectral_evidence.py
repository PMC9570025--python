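"""Consensus MALDI-TOF ion signals and predicted-mass matching.

A venom mass fingerprint is a sparse list of monoisotopic [M+H]+ signals.
Replicate fingerprints of one specimen group (male, female, juvenile) are
reduced to consensus signals by greedy single-linkage clustering in
ascending m/z, and only signals recurring in at least a configurable
fraction of the group's spectra (default 50%) are considered reproducible.
Predicted peptide masses are then matched against the consensus lists to
derive a presence/absence pattern per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean

from .mass_core import MaturePeptide

GROUPS = ("male", "female", "juvenile")

__all__ = [
    "GROUPS",
    "PeakList",
    "ConsensusSignal",
    "MassMatch",
    "consensus_signals",
    "match_predictions",
    "presence_table",
]


@dataclass(frozen=True)
class PeakList:
    """One spectrum reduced to sorted monoisotopic [M+H]+ signals."""

    specimen_id: str
    group: str
    signals: tuple[float, ...]
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")
        if any(mz <= 0 for mz in self.signals):
            raise ValueError("m/z values must be positive")
        if list(self.signals) != sorted(self.signals):
            object.__setattr__(self, "signals", tuple(sorted(self.signals)))

    @property
    def spectrum_key(self) -> tuple[str, str]:
        return (self.specimen_id, self.replicate_id)


@dataclass(frozen=True)
class ConsensusSignal:
    """A cross-spectrum cluster of recurring ion signals."""

    group: str
    centroid_mz: float
    occurrence_fraction: float
    supporting_spectra: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 <= self.occurrence_fraction <= 1:
            raise ValueError("occurrence fraction must lie in [0, 1]")


@dataclass(frozen=True)
class MassMatch:
    peptide: MaturePeptide
    signal: ConsensusSignal
    delta_da: float


def consensus_signals(
    peaklists: list[PeakList],
    tolerance_da: float,
    min_occurrence_fraction: float = 0.5,
) -> list[ConsensusSignal]:
    """Reproducible consensus signals of one specimen group.

    All signals of the group are pooled, sorted, and chained into clusters
    whenever the gap between consecutive values is at most ``tolerance_da``
    (greedy single linkage; deterministic and independent of peak-list
    order). A cluster's occurrence fraction counts distinct supporting
    spectra over the group's total spectra; clusters below
    ``min_occurrence_fraction`` are discarded.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be strictly positive")
    if not peaklists:
        return []
    groups = {pl.group for pl in peaklists}
    if len(groups) != 1:
        raise ValueError(f"peak lists span multiple groups: {sorted(groups)}")
    group = groups.pop()
    n_spectra = len({pl.spectrum_key for pl in peaklists})

    pooled = sorted(
        (mz, pl.spectrum_key) for pl in peaklists for mz in pl.signals
    )
    out: list[ConsensusSignal] = []
    cluster: list[tuple[float, tuple[str, str]]] = []

    def flush() -> None:
        if not cluster:
            return
        spectra = tuple(sorted({key for _, key in cluster}))
        frac = len(spectra) / n_spectra
        if frac >= min_occurrence_fraction:
            out.append(
                ConsensusSignal(
                    group=group,
                    centroid_mz=fmean(mz for mz, _ in cluster),
                    occurrence_fraction=frac,
                    supporting_spectra=spectra,
                )
            )

    for mz, key in pooled:
        if cluster and mz - cluster[-1][0] > tolerance_da:
            flush()
            cluster = []
        cluster.append((mz, key))
    flush()
    return out


def match_predictions(
    predicted: list[MaturePeptide],
    consensus: list[ConsensusSignal],
    tolerance_da: float,
) -> list[MassMatch]:
    """Match predicted [M+H]+ values against consensus signals.

    A peptide may match signals in several groups; within one group only
    the nearest centroid within ``tolerance_da`` is reported (inclusive
    boundary, so a zero tolerance still accepts exact equality).
    """
    if tolerance_da < 0:
        raise ValueError("tolerance must be non-negative")
    by_group: dict[str, list[ConsensusSignal]] = {}
    for sig in consensus:
        by_group.setdefault(sig.group, []).append(sig)

    matches: list[MassMatch] = []
    for pep in predicted:
        for group in sorted(by_group):
            best: ConsensusSignal | None = None
            best_delta = float("inf")
            for sig in by_group[group]:
                delta = abs(pep.predicted_mh - sig.centroid_mz)
                if delta <= tolerance_da and delta < best_delta:
                    best, best_delta = sig, delta
            if best is not None:
                matches.append(MassMatch(peptide=pep, signal=best, delta_da=best_delta))
    return matches


def presence_table(
    predicted: list[MaturePeptide],
    consensus_by_group: dict[str, list[ConsensusSignal]],
    tolerance_da: float,
) -> dict[tuple[str, str], bool]:
    """Presence of each source precursor in each group's fingerprints.

    A precursor is present in a group if any of its candidate mature
    peptides matches a consensus signal of that group.
    """
    unknown = set(consensus_by_group) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown groups {sorted(unknown)}")
    all_signals = [s for sigs in consensus_by_group.values() for s in sigs]
    matched: set[tuple[str, str]] = set()
    for m in match_predictions(predicted, all_signals, tolerance_da):
        matched.add((m.peptide.source_id, m.signal.group))
    ids = {p.source_id for p in predicted}
    return {
        (pid, group): (pid, group) in matched
        for pid in sorted(ids)
        for group in GROUPS
    }
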