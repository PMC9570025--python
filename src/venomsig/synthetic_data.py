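"""Synthetic input bundles with planted ground truth.

The generator emulates the study design the pipeline targets: a small
venom-gland species panel (2 adult males, 4 adult females, 4 juveniles,
two venom extractions each), precursors following the euscorpiid
processing grammar (signal peptide, optional propeptides, basic cleavage
sites, Gly-amidation cassettes, cysteine-rich cores with even cysteine
counts), log-normal TPM triplets spanning the observed range, and a PSM
quality table. Every emitted record is covered by a truth table, so each
pipeline stage and the end-to-end recovery of sex-specific calls can be
tested without any external data.

Sequence backgrounds use uniform residue frequencies apart from the
enforced motifs; mature cores of site-processed classes are kept free of
K/R so the planted cleavage site is the first (and only) one, and planted
masses are rejection-sampled to be at least 1 Da apart so that mass-based
presence calls are identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mass_core import MaturePeptide, mh_plus
from .maturation import PrecursorRecord, Strategy, expand_alleles, mature_candidates
from .spectral_evidence import GROUPS, PeakList
from .specificity import ExpressionTriplet, PSMRecord

__all__ = [
    "SyntheticTruth",
    "generate_precursors",
    "simulate_peaklists",
    "simulate_expression",
    "simulate_psms",
    "evaluate_recovery",
    "simulate_bundle",
]

LABELS = ("up_in_males", "down_in_males", "unspecific")

DEFAULT_CLASS_MIX = {
    "neurotoxin": 0.4,
    "AMP": 0.2,
    "enzyme": 0.1,
    "protease inhibitor": 0.1,
    "other": 0.1,
    "novel": 0.1,
}
DEFAULT_LABEL_MIX = {"up_in_males": 0.25, "down_in_males": 0.25, "unspecific": 0.5}

# specimen panel: (group, count); two replicates each by default
DEFAULT_SPECIMENS = (("male", 2), ("female", 4), ("juvenile", 4))

_HYDROPHOBIC = "AFILMVW"
# core alphabet without Cys/Lys/Arg/Gly (those are inserted deliberately)
_CORE = "ADEFHILMNPQSTVWY"
_NO_KR = _CORE + "G"

_LABEL_GROUPS = {
    "up_in_males": ("male",),
    "down_in_males": ("female", "juvenile"),
    "unspecific": ("male", "female", "juvenile"),
}


@dataclass
class SyntheticTruth:
    """Planted ground truth covering every generated record."""

    precursors: list[PrecursorRecord]
    mature: dict[str, list[MaturePeptide]]
    labels: dict[str, str]
    classes: dict[str, str]
    params: dict = field(default_factory=dict)

    @property
    def masses(self) -> dict[str, list[float]]:
        return {
            pid: [p.predicted_mh for p in peps]
            for pid, peps in self.mature.items()
        }


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _signal_peptide(rng: np.random.Generator) -> str:
    return "M" + _draw(rng, _HYDROPHOBIC + "ST", int(rng.integers(18, 25)))


def _core(
    rng: np.random.Generator,
    length: int,
    n_cys_pairs: int = 0,
    allow_kr: bool = False,
) -> str:
    alphabet = _CORE + ("KR" if allow_kr else "")
    seq = list(_draw(rng, alphabet, length))
    if n_cys_pairs:
        pos = rng.choice(length, size=2 * n_cys_pairs, replace=False)
        for p in pos:
            seq[p] = "C"
    # avoid a trailing Gly so amidation is planted only via cassettes,
    # and avoid trailing basics colliding with appended cleavage runs
    while seq[-1] in "GKR":
        seq[-1] = str(rng.choice(list("ADEFNQSTY")))
    return "".join(seq)


def _build_one(
    rng: np.random.Generator, class_label: str
) -> tuple[str, int, Strategy, str, bool]:
    """Returns (sequence, signal_end, strategy, mature, amidated)."""
    sig = _signal_peptide(rng)
    if class_label in {"neurotoxin", "enzyme", "other"}:
        pairs = int(rng.integers(2, 5)) if class_label == "neurotoxin" else 0
        kind = rng.choice(
            ["FULL_CHAIN", "FULL_CHAIN_GLY_AMIDE", "C_TERM_BASIC_CLEAVE"]
            if class_label == "neurotoxin"
            else ["FULL_CHAIN"]
        )
        core = _core(rng, int(rng.integers(30, 70)), pairs, allow_kr=kind == "FULL_CHAIN")
        if kind == "FULL_CHAIN":
            return sig + core, len(sig), Strategy.FULL_CHAIN, core, False
        if kind == "FULL_CHAIN_GLY_AMIDE":
            return sig + core + "G", len(sig), Strategy.FULL_CHAIN_GLY_AMIDE, core, True
        run = rng.choice(["KR", "RR", "RRK", "KKK"])
        amid = bool(rng.random() < 0.5)
        chain = core + ("G" if amid else "") + run
        return sig + chain, len(sig), Strategy.C_TERM_BASIC_CLEAVE, core, amid
    if class_label == "AMP":
        core = _core(rng, int(rng.integers(13, 26)))
        amid = bool(rng.random() < 0.5)
        cassette = ("G" if amid else "") + str(rng.choice(["KR", "RR"]))
        tail = _draw(rng, _NO_KR, int(rng.integers(10, 30)))
        seq = sig + core + cassette + tail
        return seq, len(sig), Strategy.N_TERM_REGION, core, amid
    if class_label == "protease inhibitor":
        core = _core(rng, int(rng.integers(40, 70)), int(rng.integers(3, 5)))
        tail = _draw(rng, _NO_KR, int(rng.integers(5, 15)))
        seq = sig + core + "GR" + tail
        return seq, len(sig), Strategy.C_TERM_BASIC_CLEAVE, core, True
    if class_label == "novel":
        spacer = _draw(rng, _NO_KR, int(rng.integers(3, 6)))
        core = _core(rng, int(rng.integers(25, 45)), 2)
        seq = sig + spacer + "R" + core + "G"
        return seq, len(sig), Strategy.N_TERM_QUADRUPLET, core, True
    raise ValueError(f"unknown class {class_label!r}")


def generate_precursors(
    n: int,
    class_mix: dict[str, float] | None = None,
    allelic_fraction: float = 0.1,
    label_mix: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    min_mass_separation_da: float = 1.0,
) -> SyntheticTruth:
    """Generate ``n`` precursors whose maturation grammar is known.

    Each precursor decomposes under its planted strategy into exactly its
    planted mature peptide(s); planted [M+H]+ values are pairwise
    separated by at least ``min_mass_separation_da``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    class_mix = dict(class_mix or DEFAULT_CLASS_MIX)
    label_mix = dict(label_mix or DEFAULT_LABEL_MIX)
    for mix, what in ((class_mix, "class"), (label_mix, "label")):
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{what} mix must sum to 1, got {total}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    classes = rng.choice(
        list(class_mix), size=n, p=list(class_mix.values())
    )
    labels = rng.choice(list(label_mix), size=n, p=list(label_mix.values()))

    precursors: list[PrecursorRecord] = []
    mature: dict[str, list[MaturePeptide]] = {}
    planted_masses: list[float] = []
    for i in range(n):
        pid = f"SYN{i + 1:04d}"
        for _attempt in range(200):
            seq, signal_end, strategy, core, amid = _build_one(rng, classes[i])
            if rng.random() < allelic_fraction and len(core) > 4:
                j = int(rng.integers(1, len(core) - 1))
                old = core[j]
                choices = [a for a in "ADEFNQSTY" if a != old]
                if old in "CG":
                    continue  # keep disulfide count and amidation intact
                new = str(rng.choice(choices))
                k = seq.rindex(core)
                seq = seq[: k + j] + f"{old}/{new}" + seq[k + j + 1:]
            rec = PrecursorRecord(
                id=pid,
                sequence=seq,
                signal_end=signal_end,
                class_label=str(classes[i]),
                processing_strategy=strategy,
            )
            peps = mature_candidates(rec, strategy)
            masses = [p.predicted_mh for p in peps]
            if all(
                abs(m - q) >= min_mass_separation_da
                for m in masses
                for q in planted_masses
            ):
                break
        else:
            raise RuntimeError("could not place a mass-separated precursor")
        precursors.append(rec)
        mature[pid] = peps
        planted_masses.extend(masses)

    return SyntheticTruth(
        precursors=precursors,
        mature=mature,
        labels={p.id: str(lbl) for p, lbl in zip(precursors, labels)},
        classes={p.id: str(c) for p, c in zip(precursors, classes)},
        params={
            "n": n,
            "class_mix": class_mix,
            "label_mix": label_mix,
            "allelic_fraction": allelic_fraction,
            "min_mass_separation_da": min_mass_separation_da,
        },
    )


def simulate_peaklists(
    truth: SyntheticTruth,
    specimens: tuple[tuple[str, int], ...] = DEFAULT_SPECIMENS,
    replicates: int = 2,
    p_detect_present: float = 0.95,
    p_detect_absent: float = 0.0,
    jitter_sd_da: float = 0.05,
    spurious_rate: float = 5.0,
    mz_range: tuple[float, float] = (800.0, 10000.0),
    seed: int | np.random.Generator = 0,
) -> list[PeakList]:
    """Per-spectrum peak lists with planted masses, jitter and noise peaks.

    A planted peptide mass appears in a spectrum with probability
    ``p_detect_present`` when the precursor's label makes it present in
    that specimen's group (``p_detect_absent`` otherwise), perturbed by
    Gaussian jitter; spurious peaks are Poisson-many, uniform over
    ``mz_range``.
    """
    if not (0 <= p_detect_present <= 1 and 0 <= p_detect_absent <= 1):
        raise ValueError("detection probabilities must lie in [0, 1]")
    if jitter_sd_da < 0:
        raise ValueError("jitter SD must be non-negative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out: list[PeakList] = []
    for group, count in specimens:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        for s in range(1, count + 1):
            specimen = f"{group[0]}{s}"
            for rep in range(1, replicates + 1):
                mzs: list[float] = []
                for pid, masses in truth.masses.items():
                    present = group in _LABEL_GROUPS[truth.labels[pid]]
                    p = p_detect_present if present else p_detect_absent
                    for m in masses:
                        if rng.random() < p:
                            mzs.append(m + rng.normal(0.0, jitter_sd_da))
                for _ in range(rng.poisson(spurious_rate)):
                    mzs.append(float(rng.uniform(*mz_range)))
                out.append(
                    PeakList(
                        specimen_id=specimen,
                        group=group,
                        replicate_id=str(rep),
                        signals=tuple(sorted(mzs)),
                    )
                )
    return out


def simulate_expression(
    truth: SyntheticTruth,
    base_tpm: float = 500.0,
    base_sigma: float = 1.5,
    fold_specific: float = 50.0,
    dispersion: float = 0.5,
    control_fraction: float = 0.02,
    seed: int | np.random.Generator = 0,
) -> dict[str, ExpressionTriplet]:
    """Log-normal TPM triplets consistent with the planted labels.

    The per-gene baseline is log-normal around ``base_tpm`` (log-SD
    ``base_sigma``, spanning roughly 5 to 60,000 TPM); the favoured sex of
    a specific precursor is scaled by ``fold_specific``; multiplicative
    log-normal noise of log-SD ``dispersion`` is applied per tissue; the
    gland-free control sits near zero (``control_fraction`` of baseline).
    """
    if fold_specific <= 1:
        raise ValueError("fold_specific must be > 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out: dict[str, ExpressionTriplet] = {}
    for p in truth.precursors:
        base = base_tpm * rng.lognormal(0.0, base_sigma)
        male = female = base
        label = truth.labels[p.id]
        if label == "up_in_males":
            male *= fold_specific
        elif label == "down_in_males":
            female *= fold_specific
        noise = rng.lognormal(0.0, dispersion, size=3) if dispersion > 0 else np.ones(3)
        out[p.id] = ExpressionTriplet(
            tpm_male_telson=float(male * noise[0]),
            tpm_female_telson=float(female * noise[1]),
            tpm_negative_control=float(base * control_fraction * noise[2]),
        )
    return out


def simulate_psms(
    truth: SyntheticTruth,
    fail_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[PSMRecord]:
    """Search-engine quality table; a ``fail_fraction`` of precursors get
    sub-threshold scores so filter behaviour can be exercised."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    exps_by_label = {
        "up_in_males": frozenset({"D-m", "ND-m"}),
        "down_in_males": frozenset({"D-m", "D-f", "ND-m", "ND-f"}),
        "unspecific": frozenset({"D-m", "D-f", "ND-m", "ND-f"}),
    }
    out = []
    for p in truth.precursors:
        failing = rng.random() < fail_fraction
        out.append(
            PSMRecord(
                precursor_id=p.id,
                neg_log_p=float(
                    rng.uniform(5, 25) if failing else rng.uniform(40, 90)
                ),
                coverage_pct=float(rng.uniform(15, 95)),
                has_signal_peptide=True,
                experiments=exps_by_label[truth.labels[p.id]],
            )
        )
    return out


def evaluate_recovery(
    calls: dict[str, str], truth: SyntheticTruth
) -> pd.DataFrame:
    """Per-label precision and recall of specificity calls against truth."""
    if set(calls) != set(truth.labels):
        raise ValueError("calls and truth must cover the same precursor ids")
    rows = []
    for label in LABELS:
        tp = sum(
            1 for pid, c in calls.items() if c == label and truth.labels[pid] == label
        )
        called = sum(1 for c in calls.values() if c == label)
        actual = sum(1 for t in truth.labels.values() if t == label)
        rows.append(
            {
                "label": label,
                "tp": tp,
                "called": called,
                "actual": actual,
                "precision": tp / called if called else float("nan"),
                "recall": tp / actual if actual else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("label")


def simulate_bundle(
    outdir: str | Path,
    n: int = 40,
    seed: int = 0,
    **kwargs,
) -> SyntheticTruth:
    """Write a complete input bundle (FASTA, annotations, peak lists,
    expression, PSMs, truth) into ``outdir``."""
    from . import io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth = generate_precursors(n, seed=rng, **kwargs)
    peaklists = simulate_peaklists(truth, seed=rng)
    expression = simulate_expression(truth, seed=rng)
    psms = simulate_psms(truth, seed=rng)

    io_formats.write_precursor_fasta(
        truth.precursors, outdir / "precursors.fasta", outdir / "annotations.tsv"
    )
    io_formats.write_peaklists(peaklists, outdir / "peaklists.tsv")
    io_formats.write_expression_table(expression, outdir / "expression.tsv")
    io_formats.write_psm_table(psms, outdir / "psms.tsv")
    pd.DataFrame(
        {
            "id": [p.id for p in truth.precursors],
            "label": [truth.labels[p.id] for p in truth.precursors],
            "class": [truth.classes[p.id] for p in truth.precursors],
            "mature": [
                ";".join(m.sequence for m in truth.mature[p.id])
                for p in truth.precursors
            ],
            "mh": [
                ";".join(f"{m.predicted_mh:.4f}" for m in truth.mature[p.id])
                for p in truth.precursors
            ],
        }
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return truth
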