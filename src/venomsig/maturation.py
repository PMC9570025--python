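"""Precursor maturation: deriving candidate bioactive peptides.

Scorpion venom precursors are pre-propeptides: an N-terminal signal
peptide, the mature peptide region, and optional propeptides separated by
proprotein-convertase cleavage sites (runs of 1-3 basic residues, K/R).
A Gly immediately preceding a cleavage site, or at the chain's C-terminus,
acts as an amidation signal and is consumed during processing.

The processing grammar implemented here covers the strategies observed in
euscorpiid venom precursors:

* ``FULL_CHAIN`` - the mature peptide is the complete chain after the
  signal peptide.
* ``FULL_CHAIN_GLY_AMIDE`` - as above, but the chain's terminal Gly is
  consumed as an amidation signal.
* ``C_TERM_BASIC_CLEAVE`` - the mature peptide ends immediately before a
  basic run (mono-, di- or tribasic); a Gly preceding the run amidates.
* ``N_TERM_REGION`` - the mature peptide spans from the chain start to the
  first cleavage site; Gly-amidation and trailing-basic trimming apply.
* ``N_TERM_QUADRUPLET`` - the mature peptide follows a monobasic Arg that
  is itself preceded by a short (>= 3 residue) spacer after the signal
  peptide; the chain's terminal Gly amidates.

Single Lys residues are reported as monobasic runs but are not used as
cleavage points: monobasic proprotein-convertase cleavage occurs after
Arg, and treating every lone Lys as a site would shred Lys-rich mature
peptides. All cysteines of a product are assumed paired (disulfide count
= floor(#C / 2)).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum

from .mass_core import MaturePeptide, STANDARD_RESIDUES, count_disulfides

logger = logging.getLogger(__name__)

__all__ = [
    "PrecursorRecord",
    "CleavageSite",
    "Strategy",
    "strip_signal",
    "find_basic_sites",
    "apply_processing",
    "expand_alleles",
]

CLASS_LABELS = {
    "neurotoxin",
    "AMP",
    "enzyme",
    "protease inhibitor",
    "other",
    "novel",
}

_ALLELE_RE = re.compile(r"([A-Z])/([A-Z])")


class Strategy(str, Enum):
    FULL_CHAIN = "FULL_CHAIN"
    FULL_CHAIN_GLY_AMIDE = "FULL_CHAIN_GLY_AMIDE"
    C_TERM_BASIC_CLEAVE = "C_TERM_BASIC_CLEAVE"
    N_TERM_REGION = "N_TERM_REGION"
    N_TERM_QUADRUPLET = "N_TERM_QUADRUPLET"
    AUTO = "AUTO"


@dataclass(frozen=True)
class PrecursorRecord:
    """A venom precursor with its signal-peptide boundary.

    ``sequence`` may contain one allelic position written ``X/Y``
    (e.g. ``...EKEK/EKE...``); coordinates such as ``signal_end`` refer to
    the expanded, plain sequence (both alleles have equal length).
    ``signal_end`` is the 0-based index of the first mature-chain residue.
    """

    id: str
    sequence: str
    signal_end: int
    class_label: str = "other"
    processing_strategy: Strategy | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("precursor id must be non-empty")
        plain = _ALLELE_RE.sub(lambda m: m.group(1), self.sequence)
        bad = set(plain) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"precursor {self.id!r}: non-standard residue(s) {sorted(bad)}"
            )
        if self.sequence.count("/") > 1:
            raise ValueError(
                f"precursor {self.id!r}: more than one allelic position"
            )
        if not 0 < self.signal_end < len(plain):
            raise ValueError(
                f"precursor {self.id!r}: signal_end {self.signal_end} out of "
                f"range for length {len(plain)}"
            )
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"precursor {self.id!r}: unknown class {self.class_label!r}"
            )

    @property
    def alleles(self) -> list[str]:
        return expand_alleles(self.sequence)


@dataclass(frozen=True)
class CleavageSite:
    """A maximal basic (K/R) run acting as a potential cleavage site."""

    position: int  # 0-based index of the run's first residue in the chain
    kind: str  # monobasic | dibasic | tribasic | quadruplet
    basic_run_length: int = field(default=1)

    def __post_init__(self) -> None:
        if not 1 <= self.basic_run_length <= 3:
            raise ValueError("basic run length must be 1-3")
        expected = {1: ("monobasic", "quadruplet"), 2: ("dibasic",), 3: ("tribasic",)}
        if self.kind not in expected[self.basic_run_length]:
            raise ValueError(f"kind {self.kind!r} inconsistent with run length")


def expand_alleles(sequence: str) -> list[str]:
    """Expand one ``X/Y`` allelic marker into the two plain sequences."""
    if sequence.count("/") > 1:
        raise ValueError("at most one allelic position is supported")
    m = _ALLELE_RE.search(sequence)
    if m is None:
        if "/" in sequence:
            raise ValueError(f"malformed allelic marker in {sequence!r}")
        return [sequence]
    a = sequence[: m.start()] + m.group(1) + sequence[m.end():]
    b = sequence[: m.start()] + m.group(2) + sequence[m.end():]
    return [a, b]


def strip_signal(precursor: PrecursorRecord, allele: str | None = None) -> str:
    """Remove the signal peptide, returning the mature chain."""
    seq = allele if allele is not None else expand_alleles(precursor.sequence)[0]
    if not 0 < precursor.signal_end < len(seq):
        raise ValueError(
            f"signal_end {precursor.signal_end} leaves no mature chain"
        )
    return seq[precursor.signal_end:]


def find_basic_sites(chain: str) -> list[CleavageSite]:
    """Maximal K/R runs in the chain, classified by length.

    Runs longer than three are not part of the observed processing
    repertoire; they are reported as a tribasic site over the run's three
    C-terminal residues, with a warning. A monobasic Arg preceded by at
    least three residues is additionally flagged ``quadruplet`` (the
    four-residue motif ends at the Arg).
    """
    sites: list[CleavageSite] = []
    for m in re.finditer(r"[KR]+", chain):
        start, end = m.start(), m.end()
        length = end - start
        if length > 3:
            logger.warning(
                "basic run of length %d at %d treated as tribasic", length, start
            )
            start, length = end - 3, 3
        if length == 3:
            kind = "tribasic"
        elif length == 2:
            kind = "dibasic"
        else:
            kind = (
                "quadruplet"
                if chain[start] == "R" and start >= 3
                else "monobasic"
            )
        sites.append(CleavageSite(position=start, kind=kind, basic_run_length=length))
    return sites


def _cleavable(site: CleavageSite, chain: str) -> bool:
    # single K is not a convertase cleavage point; single R is
    if site.basic_run_length >= 2:
        return True
    return chain[site.position] == "R"


def _product(
    source_id: str,
    sequence: str,
    amidated: bool,
    derivation: str,
) -> MaturePeptide:
    return MaturePeptide(
        source_id=source_id,
        sequence=sequence,
        amidated=amidated,
        n_disulfides=count_disulfides(sequence),
        derivation=derivation,
    )


def _gly_amide(segment: str) -> tuple[str, bool]:
    if segment.endswith("G") and len(segment) > 1:
        return segment[:-1], True
    return segment, False


def apply_processing(
    chain: str,
    strategy: Strategy | str = Strategy.AUTO,
    *,
    source_id: str = "",
    trim_basic_residues: bool = True,
) -> list[MaturePeptide]:
    """Candidate mature peptides of one chain under one strategy.

    An inapplicable strategy (e.g. Gly-amidation of a chain not ending in
    Gly) yields an empty list with a logged reason rather than an error,
    so that AUTO enumeration degrades gracefully.
    """
    strategy = Strategy(strategy)
    if not chain:
        raise ValueError("empty mature chain")
    sites = [s for s in find_basic_sites(chain) if _cleavable(s, chain)]
    out: list[MaturePeptide] = []

    def full_chain() -> None:
        out.append(_product(source_id, chain, False, "FULL_CHAIN"))

    def full_chain_gly() -> None:
        if not chain.endswith("G") or len(chain) < 2:
            logger.info("%s: chain does not end in Gly; GLY_AMIDE skipped", source_id)
            return
        out.append(_product(source_id, chain[:-1], True, "FULL_CHAIN_GLY_AMIDE"))

    def c_term_cleave() -> None:
        if not sites:
            logger.info("%s: no basic run; C_TERM_BASIC_CLEAVE skipped", source_id)
        for s in sites:
            prefix = chain[: s.position]
            if not prefix:
                continue
            seq, amid = _gly_amide(prefix)
            out.append(
                _product(
                    source_id, seq, amid, f"C_TERM_BASIC_CLEAVE@{s.position}:{s.kind}"
                )
            )

    def n_term_region() -> None:
        if not sites:
            logger.info("%s: no basic site; N_TERM_REGION skipped", source_id)
            return
        s = sites[0]
        prefix = chain[: s.position]
        if not prefix:
            logger.info("%s: first site at chain start; N_TERM_REGION empty", source_id)
            return
        if trim_basic_residues and prefix[-1] in "KR" and len(prefix) > 1:
            prefix = prefix[:-1]
        seq, amid = _gly_amide(prefix)
        out.append(
            _product(source_id, seq, amid, f"N_TERM_REGION@{s.position}:{s.kind}")
        )

    def n_term_quadruplet() -> None:
        # first Arg with a >= 3-residue spacer between signal end and Arg
        idx = next(
            (i for i, aa in enumerate(chain) if aa == "R" and i >= 3), None
        )
        if idx is None or idx + 1 >= len(chain):
            logger.info("%s: no quadruplet Arg; N_TERM_QUADRUPLET skipped", source_id)
            return
        segment = chain[idx + 1:]
        seq, amid = _gly_amide(segment)
        out.append(_product(source_id, seq, amid, f"N_TERM_QUADRUPLET@{idx}"))

    dispatch = {
        Strategy.FULL_CHAIN: (full_chain,),
        Strategy.FULL_CHAIN_GLY_AMIDE: (full_chain_gly,),
        Strategy.C_TERM_BASIC_CLEAVE: (c_term_cleave,),
        Strategy.N_TERM_REGION: (n_term_region,),
        Strategy.N_TERM_QUADRUPLET: (n_term_quadruplet,),
        Strategy.AUTO: (
            full_chain,
            full_chain_gly,
            n_term_region,
            n_term_quadruplet,
            c_term_cleave,
        ),
    }
    for step in dispatch[strategy]:
        step()

    # collapse duplicates (identical sequence and amidation state)
    seen: set[tuple[str, bool]] = set()
    unique: list[MaturePeptide] = []
    for p in out:
        key = (p.sequence, p.amidated)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique


def mature_candidates(
    precursor: PrecursorRecord,
    strategy: Strategy | str | None = None,
    *,
    trim_basic_residues: bool = True,
) -> list[MaturePeptide]:
    """All candidate products of a precursor, across its alleles.

    If ``strategy`` is None, the precursor's annotated strategy is used
    when present, otherwise AUTO enumeration.
    """
    if strategy is None:
        strategy = precursor.processing_strategy or Strategy.AUTO
    products: list[MaturePeptide] = []
    alleles = expand_alleles(precursor.sequence)
    for i, allele in enumerate(alleles):
        tag = f"|allele{i}" if len(alleles) > 1 else ""
        chain = strip_signal(precursor, allele)
        for p in apply_processing(
            chain,
            strategy,
            source_id=precursor.id,
            trim_basic_residues=trim_basic_residues,
        ):
            products.append(
                MaturePeptide(
                    source_id=p.source_id,
                    sequence=p.sequence,
                    amidated=p.amidated,
                    n_disulfides=p.n_disulfides,
                    derivation=p.derivation + tag,
                )
            )
    # alleles can coincide outside the variant position's window
    seen: set[tuple[str, bool]] = set()
    unique: list[MaturePeptide] = []
    for p in products:
        key = (p.sequence, p.amidated)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique
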