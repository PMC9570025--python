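"""Readers/writers for the pipeline's external formats, and run config.

All tabular formats are TSV; precursor sequences travel as FASTA with a
companion annotation table (or ``key=value`` pairs in the FASTA header).
Peak lists are plain text extracted from spectra — one row per ion
signal — because the analysis operates on monoisotopic [M+H]+ lists, not
on profile spectra.

The packaged fixture (``data/table1_fixture.tsv``) encodes the twelve
euscorpiid venom precursors with their printed mature regions, PTM flags,
predicted masses, TPM triplets and MALDI regulation arrows; it is loaded
with :func:`load_table1_fixture`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .maturation import PrecursorRecord, Strategy
from .spectral_evidence import GROUPS, PeakList
from .specificity import ExpressionTriplet, HomologyHit, PSMRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_precursor_fasta",
    "write_precursor_fasta",
    "read_peaklists",
    "write_peaklists",
    "read_expression_table",
    "write_expression_table",
    "read_psm_table",
    "write_psm_table",
    "read_homology_table",
    "write_homology_table",
    "load_table1_fixture",
    "write_provenance_log",
]


@dataclass(frozen=True)
class RunConfig:
    """Tunable thresholds of one analysis run.

    Defaults follow the published evidence filters: PSMs are kept only
    above -10lgP 30 and 7% coverage (strict inequalities), and a MALDI
    consensus signal must recur in at least half of a group's spectra.
    """

    mass_tolerance_da: float = 0.2
    cluster_tolerance_da: float = 0.15
    min_occurrence_fraction: float = 0.5
    min_neg_log_p: float = 30.0
    min_coverage_pct: float = 7.0
    min_fold_change: float = 2.0
    trim_basic_residues: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.mass_tolerance_da <= 0 or self.cluster_tolerance_da <= 0:
            raise ValueError("tolerances must be strictly positive")
        if not 0 <= self.min_occurrence_fraction <= 1:
            raise ValueError("min_occurrence_fraction must lie in [0, 1]")
        if self.min_fold_change < 1:
            raise ValueError("min_fold_change must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# precursors

_HEADER_KEYS = ("signal_end", "class_label", "strategy")


def read_precursor_fasta(
    path: str | Path, annotations: str | Path | None = None
) -> list[PrecursorRecord]:
    """Read precursors from FASTA plus a companion annotation table.

    The annotation TSV has columns ``id``, ``signal_end`` and optionally
    ``class_label`` and ``strategy``; alternatively the same keys may be
    embedded in the FASTA description as ``key=value`` tokens. Sequences
    may contain one allelic position written ``X/Y``.
    """
    ann: dict[str, dict[str, object]] = {}
    if annotations is not None:
        tab = pd.read_csv(annotations, sep="\t", dtype={"id": str})
        if "id" not in tab.columns or "signal_end" not in tab.columns:
            raise ValueError("annotation table needs 'id' and 'signal_end' columns")
        for row in tab.itertuples(index=False):
            ann[row.id] = row._asdict()

    records: list[PrecursorRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate precursor identifier {rec.id!r}")
        seen.add(rec.id)
        meta: dict[str, object] = {}
        for token in rec.description.split():
            if "=" in token:
                k, _, v = token.partition("=")
                if k in _HEADER_KEYS:
                    meta[k] = v
        meta.update(ann.get(rec.id, {}))
        if "signal_end" not in meta:
            raise ValueError(f"precursor {rec.id!r}: no signal_end annotation")
        strategy = meta.get("strategy")
        if isinstance(strategy, float) and pd.isna(strategy):
            strategy = None
        records.append(
            PrecursorRecord(
                id=rec.id,
                sequence=str(rec.seq),
                signal_end=int(meta["signal_end"]),
                class_label=str(meta.get("class_label", "other")),
                processing_strategy=Strategy(strategy) if strategy else None,
            )
        )
    if not records:
        logger.warning("no records parsed from %s", path)
    return records


def write_precursor_fasta(
    records: list[PrecursorRecord], fasta_path: str | Path,
    annotations_path: str | Path,
) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "signal_end": [r.signal_end for r in records],
            "class_label": [r.class_label for r in records],
            "strategy": [
                r.processing_strategy.value if r.processing_strategy else ""
                for r in records
            ],
        }
    ).to_csv(annotations_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peak lists

def read_peaklists(path: str | Path) -> list[PeakList]:
    """Read MALDI peak lists from a TSV of (specimen, group, replicate, mz).

    One :class:`PeakList` per (specimen, replicate); exact duplicate m/z
    values within one spectrum are merged; values are sorted ascending.
    An intensity column, if present, is ignored for presence calls.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"specimen": str, "replicate": str})
    required = {"specimen", "group", "replicate", "mz"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"peak-list table missing columns {sorted(missing)}")
    bad = set(tab["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group label(s) {sorted(bad)}")
    if (tab["mz"].dropna() <= 0).any():
        raise ValueError("non-positive m/z value in peak list")
    out: list[PeakList] = []
    for (specimen, group, replicate), sub in tab.groupby(
        ["specimen", "group", "replicate"], sort=True
    ):
        mzs = sorted(set(float(v) for v in sub["mz"].dropna()))
        out.append(
            PeakList(
                specimen_id=str(specimen),
                group=str(group),
                replicate_id=str(replicate),
                signals=tuple(mzs),
            )
        )
    return out


def write_peaklists(peaklists: list[PeakList], path: str | Path) -> None:
    rows = [
        {
            "specimen": pl.specimen_id,
            "group": pl.group,
            "replicate": pl.replicate_id,
            "mz": mz,
        }
        for pl in peaklists
        for mz in pl.signals
    ]
    cols = ["specimen", "group", "replicate", "mz"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression

def _tpm(value: object) -> float:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return 0.0
    if isinstance(value, str):
        value = value.strip().replace(",", "")
        if value in {"", "-"}:
            return 0.0
    v = float(value)
    if v < 0:
        raise ValueError(f"negative TPM value {v}")
    return v


def read_expression_table(path: str | Path) -> dict[str, ExpressionTriplet]:
    """Read TPM triplets; '-' and empty cells mean no detected expression."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "tpm_male", "tpm_female", "tpm_control"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    return {
        row.id: ExpressionTriplet(
            tpm_male_telson=_tpm(row.tpm_male),
            tpm_female_telson=_tpm(row.tpm_female),
            tpm_negative_control=_tpm(row.tpm_control),
        )
        for row in tab.itertuples(index=False)
    }


def write_expression_table(
    triplets: dict[str, ExpressionTriplet], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "id": list(triplets),
            "tpm_male": [t.tpm_male_telson for t in triplets.values()],
            "tpm_female": [t.tpm_female_telson for t in triplets.values()],
            "tpm_control": [t.tpm_negative_control for t in triplets.values()],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PSM evidence

def read_psm_table(path: str | Path) -> list[PSMRecord]:
    tab = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "neg_log_p", "coverage_pct", "has_signal_peptide"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"PSM table missing columns {sorted(missing)}")
    out = []
    for row in tab.itertuples(index=False):
        exps = getattr(row, "experiments", "")
        if isinstance(exps, float) and pd.isna(exps):
            exps = ""
        out.append(
            PSMRecord(
                precursor_id=row.id,
                neg_log_p=float(row.neg_log_p),
                coverage_pct=float(row.coverage_pct),
                has_signal_peptide=bool(row.has_signal_peptide),
                experiments=frozenset(e for e in str(exps).split(",") if e),
            )
        )
    return out


def write_psm_table(records: list[PSMRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [r.precursor_id for r in records],
            "neg_log_p": [r.neg_log_p for r in records],
            "coverage_pct": [r.coverage_pct for r in records],
            "has_signal_peptide": [r.has_signal_peptide for r in records],
            "experiments": [",".join(sorted(r.experiments)) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# homology hits

def read_homology_table(path: str | Path) -> dict[str, list[HomologyHit]]:
    tab = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "database", "description", "e_value"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"homology table missing columns {sorted(missing)}")
    out: dict[str, list[HomologyHit]] = {}
    for row in tab.itertuples(index=False):
        out.setdefault(row.id, []).append(
            HomologyHit(
                database=str(row.database),
                description=str(row.description),
                e_value=float(row.e_value),
            )
        )
    return out


def write_homology_table(
    hits: dict[str, list[HomologyHit]], path: str | Path
) -> None:
    rows = [
        {
            "id": pid,
            "database": h.database,
            "description": h.description,
            "e_value": h.e_value,
        }
        for pid, hs in hits.items()
        for h in hs
    ]
    cols = ["id", "database", "description", "e_value"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged fixture

def load_table1_fixture() -> pd.DataFrame:
    """The twelve-precursor fixture with printed masses and TPM triplets.

    Columns include the precursor sequence (with allelic ``X/Y`` markers),
    signal-peptide boundary, the displayed mature region, PTM flags,
    printed predicted [M+H]+ (slash-separated for allelic pairs), the TPM
    triplet, the BLAST-hit description, the Orbitrap experiment tags and
    the MALDI regulation arrow.
    """
    ref = resources.files("venomsig").joinpath("data/table1_fixture.tsv")
    with resources.as_file(ref) as p:
        tab = pd.read_csv(p, sep="\t", dtype=str)
    if len(tab) != 12:
        raise RuntimeError("fixture must contain exactly 12 precursor rows")
    for col in ("tpm_male", "tpm_female", "tpm_control"):
        tab[col] = [_tpm(v) for v in tab[col]]
    tab["signal_end"] = tab["signal_end"].astype(int)
    tab["n_disulfides"] = tab["n_disulfides"].astype(int)
    tab["amidated"] = tab["amidated"].map({"True": True, "False": False})
    if not set(tab["arrow"]) <= {"↑", "↓"}:
        raise RuntimeError("fixture arrows must be ↑ or ↓")
    return tab


def fixture_precursors(tab: pd.DataFrame | None = None) -> list[PrecursorRecord]:
    """PrecursorRecord objects for the packaged fixture rows."""
    if tab is None:
        tab = load_table1_fixture()
    return [
        PrecursorRecord(
            id=row.name_,
            sequence=row.precursor,
            signal_end=int(row.signal_end),
            class_label=row.class_label,
            processing_strategy=Strategy(row.strategy),
        )
        for row in tab.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# provenance

def write_provenance_log(
    path: str | Path,
    config: RunConfig,
    inputs: dict[str, str | Path] | None = None,
    extra: dict[str, object] | None = None,
) -> None:
    """JSON log of config, seed and input digests for one run."""
    digests = {}
    for name, p in (inputs or {}).items():
        h = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        digests[name] = {"path": str(p), "sha256": h}
    payload = {
        "config": dataclasses.asdict(config),
        "inputs": digests,
        **(extra or {}),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
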