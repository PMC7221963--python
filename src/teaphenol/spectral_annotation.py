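"""Rule-based annotation of negative-mode MS/MS spectra of tea polyphenols.

The engine mirrors how an analyst reads a QqTOF MS/MS spectrum of a green-tea
extract: find neutral-loss relationships between the precursor and fragment
ions (glycosyl residues, acyl residues, small molecules, ring-fission losses),
look for diagnostic ions (flavanol A-ring at m/z 125.02, retro-Diels-Alder
pair 137/151, gallate at 169.01, free and radical aglycone ions), and combine
the evidence into a compound-class call.

Class vocabulary: flavan-3-ol, galloylated flavan-3-ol, proanthocyanidin
dimer, flavonol O-glycoside, acylated flavonol glycoside, flavone C-glycoside,
phenolic acid/quinate ester, saccharide, amino acid, unclassified.

Key diagnostic logic
--------------------
* Radical aglycone dominance ([A−2H]•− more intense than [A−H]−) after loss of
  a dehydrated sugar residue localizes the glycosylation at the flavonol 3-OH.
* C-glycosides shed 60/90/120 Da cross-ring fragments of the sugar instead of
  the whole residue; two or more such losses with no free-aglycone-producing
  glycosyl loss call a C-glycoside.
* Acylated glycosides show the acyl-acid / acid−H2O loss pair (e.g. coumaric
  acid 164.05 and coumaroyl 146.04) or a galloyl loss next to an aglycone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .formula_mass import (
    ElementalFormula,
    deprotonated_mz,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    radical_mz,
    rdb,
    round_half_up,
)

__all__ = [
    "Peak",
    "MsmsSpectrum",
    "NeutralLossRule",
    "LossAssignment",
    "DiagnosticIon",
    "AglyconeReference",
    "AnnotationResult",
    "CompoundLibraryEntry",
    "DEFAULT_LOSS_RULES",
    "DIAGNOSTIC_IONS",
    "AGLYCONES",
    "COMPOUND_CLASSES",
    "load_compound_library",
    "detect_neutral_losses",
    "identify_aglycone",
    "detect_c_glycoside",
    "classify_compound",
    "annotate_library",
    "class_relative_abundance",
]

#: Default fragment m/z matching tolerance, Da. Measured QqTOF fragment values
#: deviate from exact residue masses by up to ~15 mDa at the low-mass end.
DEFAULT_FRAGMENT_TOL = 0.02

#: Default precursor matching tolerance for library lookup, ppm.
DEFAULT_PRECURSOR_TOL_PPM = 10.0

#: Fragments below this fraction of the base peak are ignored by default.
DEFAULT_INTENSITY_FLOOR = 0.01

COMPOUND_CLASSES = (
    "flavan-3-ol",
    "galloylated flavan-3-ol",
    "proanthocyanidin dimer",
    "flavonol O-glycoside",
    "acylated flavonol glycoside",
    "flavone C-glycoside",
    "phenolic acid/quinate ester",
    "saccharide",
    "amino acid",
    "unclassified",
)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class MsmsSpectrum:
    """A precursor with its fragment peak list, sorted by ascending m/z."""

    precursor_mz: float
    peaks: Sequence[Peak]
    rt: Optional[float] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        peaks = sorted((p if isinstance(p, Peak) else Peak(*p) for p in self.peaks),
                       key=lambda p: p.mz)
        for p in peaks:
            if p.mz > self.precursor_mz + 0.5:
                raise ValueError(
                    f"fragment m/z {p.mz} exceeds precursor {self.precursor_mz}")
        self.peaks = peaks

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    def above_floor(self, floor_fraction: float) -> list[Peak]:
        """Peaks at or above ``floor_fraction`` of the base peak."""
        cutoff = floor_fraction * self.base_peak_intensity
        return [p for p in self.peaks if p.intensity >= cutoff]

    def scaled(self, factor: float) -> "MsmsSpectrum":
        return MsmsSpectrum(self.precursor_mz,
                            [Peak(p.mz, p.intensity * factor) for p in self.peaks],
                            rt=self.rt, sample_id=self.sample_id)


@dataclass(frozen=True)
class NeutralLossRule:
    """A named neutral loss with its elemental composition and exact mass."""

    name: str
    formula: ElementalFormula
    category: str  # glycosyl | acyl | small | ring-fission

    @property
    def exact_mass(self) -> float:
        return monoisotopic_mass(self.formula)


def _rule(name: str, formula: str, category: str) -> NeutralLossRule:
    return NeutralLossRule(name, parse_formula(formula), category)


#: Neutral losses an analyst looks for in tea-polyphenol spectra. Exact masses
#: are derived from the formulas (hexose 162.0528, deoxyhexose 146.0579,
#: pentose 132.0423, galloyl 152.0110, coumaroyl 146.0368, ...).
DEFAULT_LOSS_RULES: tuple[NeutralLossRule, ...] = (
    _rule("hexose", "C6H10O5", "glycosyl"),
    _rule("deoxyhexose", "C6H10O4", "glycosyl"),
    _rule("pentose", "C5H8O4", "glycosyl"),
    _rule("galloyl", "C7H4O4", "acyl"),
    _rule("coumaroyl", "C9H6O2", "acyl"),
    _rule("coumaric acid", "C9H8O3", "acyl"),
    _rule("gallic acid", "C7H6O5", "acyl"),
    _rule("methylgalloyl", "C8H6O4", "acyl"),
    _rule("water", "H2O", "small"),
    _rule("carbon dioxide", "CO2", "small"),
    _rule("ethenone", "C2H2O", "small"),
    _rule("formaldehyde", "CH2O", "small"),
    _rule("formic acid", "CH2O2", "small"),
    _rule("A-ring (HRF)", "C6H6O3", "ring-fission"),
    _rule("cross-ring 60", "C2H4O2", "ring-fission"),
    _rule("cross-ring 90", "C3H6O3", "ring-fission"),
    _rule("cross-ring 120", "C4H8O4", "ring-fission"),
)

_CROSS_RING_NAMES = ("cross-ring 60", "cross-ring 90", "cross-ring 120")
_GALLOYLATION_LOSSES = ("galloyl", "gallic acid", "methylgalloyl")


@dataclass(frozen=True)
class DiagnosticIon:
    name: str
    mz: float
    meaning: str


def _frag_mz(formula: str, radical: bool = False) -> float:
    f = parse_formula(formula)
    return radical_mz(f) if radical else deprotonated_mz(f)


#: Non-aglycone diagnostic fragment ions (m/z derived from their formulas,
#: except the methylgallate-derived radical which is an empirical landmark).
DIAGNOSTIC_IONS: tuple[DiagnosticIon, ...] = (
    DiagnosticIon("flavanol A-ring", _frag_mz("C6H6O3"), "flavanol HRF A-ring"),
    DiagnosticIon("RDA 137", _frag_mz("C7H6O3"), "retro-Diels-Alder A-ring"),
    DiagnosticIon("RDA 151", _frag_mz("C8H8O3"), "retro-Diels-Alder fragment"),
    DiagnosticIon("catechol B-ring", _frag_mz("C6H6O2"), "catechol B-ring"),
    DiagnosticIon("gallate", _frag_mz("C7H6O5"), "deprotonated gallic acid"),
    DiagnosticIon("methylgallate radical", 168.0070, "methyl gallate derived radical"),
    DiagnosticIon("quinate", _frag_mz("C7H12O6"), "deprotonated quinic acid"),
)

_DIAG_BY_NAME = {d.name: d for d in DIAGNOSTIC_IONS}
_AROMATIC_DIAGNOSTICS = tuple(d for d in DIAGNOSTIC_IONS if d.name != "quinate")


@dataclass(frozen=True)
class AglyconeReference:
    """Even-electron [A−H]− and radical [A−2H]•− masses of a flavonoid aglycone."""

    name: str
    formula: ElementalFormula
    even_mz: float
    radical_mz: Optional[float]


def _aglycone(name: str, formula: str, with_radical: bool = True) -> AglyconeReference:
    f = parse_formula(formula)
    return AglyconeReference(name, f, deprotonated_mz(f),
                             radical_mz(f) if with_radical else None)


AGLYCONES: tuple[AglyconeReference, ...] = (
    _aglycone("quercetin", "C15H10O7"),
    _aglycone("kaempferol", "C15H10O6"),
    _aglycone("myricetin", "C15H10O8"),
    _aglycone("methylkaempferol", "C16H12O6"),
    # apigenin appears only as C-glycoside; no radical channel is expected
    _aglycone("apigenin", "C15H10O5", with_radical=False),
)

_GLYCOSYL_RESIDUES = {r.name: r.exact_mass for r in DEFAULT_LOSS_RULES
                      if r.category == "glycosyl"}


@dataclass(frozen=True)
class LossAssignment:
    """One matched neutral loss between two ions of a spectrum."""

    rule: NeutralLossRule
    from_mz: float
    to_mz: float
    delta: float
    from_precursor: bool


@dataclass(frozen=True)
class AglyconeMatch:
    name: str
    evidence: str  # "3-O" | "indeterminate"
    even_peak: Optional[Peak]
    radical_peak: Optional[Peak]
    confidence: float
    reference: AglyconeReference


@dataclass
class AnnotationResult:
    compound_class: str
    aglycone: Optional[str]
    loss_chain: list[tuple[str, float, float, float]]
    diagnostic_hits: list[tuple[str, float, Peak]]
    position_evidence: str  # "3-O" | "indeterminate" | "C-C"
    score: float
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class {self.compound_class!r}")
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ValueError("score must lie in [0, 1]")


@dataclass(frozen=True)
class CompoundLibraryEntry:
    """One reference compound: identity, formula and expected MS/MS fragments."""

    peak_no: int
    rt: float
    name: str
    formula: ElementalFormula
    compound_class: str
    aglycone: Optional[str]
    expected_fragments: tuple[float, ...]
    found_mz: float
    calc_mz_printed: float
    error_ppm_printed: float
    rdb_printed: float

    @property
    def calc_mz(self) -> float:
        """Recomputed [M−H]− m/z from the formula (full precision)."""
        return deprotonated_mz(self.formula)


def load_compound_library(path=None) -> list[CompoundLibraryEntry]:
    """Load the built-in (or a user-supplied) compound library CSV.

    The shipped library covers 42 green-tea constituents: saccharides,
    theanine, phenolic acids and quinate esters, catechins and their gallates,
    a proanthocyanidin dimer, flavone C-glycosides, and flavonol O-glycosides
    with and without galloyl/coumaroyl acylation.
    """
    if path is None:
        with resources.as_file(resources.files("teaphenol.data") / "compound_library.csv") as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    entries = []
    for row in table.itertuples(index=False):
        aglycone = None if pd.isna(row.aglycone) else str(row.aglycone)
        frags = tuple(float(x) for x in str(row.fragments).split(";"))
        entries.append(CompoundLibraryEntry(
            peak_no=int(row.peak), rt=float(row.rt_min), name=str(row.name),
            formula=parse_formula(str(row.formula)),
            compound_class=str(row.compound_class), aglycone=aglycone,
            expected_fragments=frags, found_mz=float(row.found_mz),
            calc_mz_printed=float(row.calc_mz_printed),
            error_ppm_printed=float(row.error_ppm_printed),
            rdb_printed=float(row.rdb_printed)))
    return entries


# ---------------------------------------------------------------------------
# neutral-loss detection
# ---------------------------------------------------------------------------

def detect_neutral_losses(
    spectrum: MsmsSpectrum,
    rules: Sequence[NeutralLossRule] = DEFAULT_LOSS_RULES,
    tol: float = DEFAULT_FRAGMENT_TOL,
    *,
    intensity_floor: float = 0.0,
) -> list[LossAssignment]:
    """Match every ordered ion pair against the neutral-loss rule set.

    Pairs include precursor→fragment and fragment→fragment (heavier to
    lighter). All rules within ``tol`` of the observed mass difference are
    reported; the result is sorted by descending parent m/z, then descending
    child m/z, then rule mass.
    """
    if not rules:
        raise ValueError("empty neutral-loss rule set")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    peaks = spectrum.above_floor(intensity_floor) if intensity_floor else list(spectrum.peaks)
    parents: list[tuple[float, bool]] = [(spectrum.precursor_mz, True)]
    parents += [(p.mz, False) for p in peaks]
    out: list[LossAssignment] = []
    for (parent, is_prec) in parents:
        for child in peaks:
            # skip the peak standing in for the (possibly mass-shifted) precursor
            delta = parent - child.mz
            if delta <= tol:
                continue
            for rule in rules:
                if abs(delta - rule.exact_mass) <= tol:
                    out.append(LossAssignment(rule, parent, child.mz, delta, is_prec))
    out.sort(key=lambda a: (-a.from_mz, -a.to_mz, -a.rule.exact_mass))
    return out


def _find_peak(peaks: Iterable[Peak], mz: float, tol: float) -> Optional[Peak]:
    best, best_d = None, tol
    for p in peaks:
        d = abs(p.mz - mz)
        if d <= best_d:
            best, best_d = p, d
    return best


# ---------------------------------------------------------------------------
# aglycone and C-glycoside evidence
# ---------------------------------------------------------------------------

def identify_aglycone(
    spectrum: MsmsSpectrum,
    tol: float = DEFAULT_FRAGMENT_TOL,
    *,
    intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
) -> Optional[AglyconeMatch]:
    """Match the low-mass region against known flavonoid aglycone ion pairs.

    Strict radical dominance ([A−2H]•− intensity > [A−H]−) is reported as
    ``"3-O"`` glycosylation evidence; an even-electron-only (or tied) match is
    ``"indeterminate"``. Candidates with both ions of the pair present win over
    single-ion matches; remaining ties go to the higher summed intensity.
    Confirmatory CH2O / CH2O2 sub-losses from the even-electron aglycone raise
    the reported confidence.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    peaks = spectrum.above_floor(intensity_floor)
    candidates: list[AglyconeMatch] = []
    for ref in AGLYCONES:
        even = _find_peak(peaks, ref.even_mz, tol)
        rad = _find_peak(peaks, ref.radical_mz, tol) if ref.radical_mz else None
        if even is None and rad is None:
            continue
        if rad is not None and (even is None or rad.intensity > even.intensity):
            evidence = "3-O"
        else:
            evidence = "indeterminate"
        confidence = 0.5
        if even is not None and rad is not None:
            confidence += 0.25
        sublosses = 0
        if even is not None:
            for sub in ("CH2O", "CH2O2"):
                if _find_peak(peaks, even.mz - monoisotopic_mass(parse_formula(sub)), tol):
                    sublosses += 1
        confidence += 0.125 * sublosses
        candidates.append(AglyconeMatch(ref.name, evidence, even, rad,
                                        min(confidence, 1.0), ref))
    if not candidates:
        return None

    def rank(m: AglyconeMatch) -> tuple:
        both = m.even_peak is not None and m.radical_peak is not None
        total = sum(p.intensity for p in (m.even_peak, m.radical_peak) if p)
        return (both, total)

    return max(candidates, key=rank)


def detect_c_glycoside(
    spectrum: MsmsSpectrum,
    tol: float = DEFAULT_FRAGMENT_TOL,
    *,
    intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
    losses: Optional[Sequence[LossAssignment]] = None,
) -> tuple[bool, list[LossAssignment]]:
    """Test for C-C-linked sugars via cross-ring losses of 60/90/120 Da.

    Returns ``True`` iff at least two distinct cross-ring losses from the
    precursor are matched AND no whole glycosyl-residue loss terminating at a
    free aglycone ion is present (which would instead indicate O-glycosylation,
    making the two calls mutually exclusive on the same evidence).
    """
    if losses is None:
        losses = detect_neutral_losses(spectrum, tol=tol, intensity_floor=intensity_floor)
    cross = [a for a in losses
             if a.from_precursor and a.rule.name in _CROSS_RING_NAMES]
    distinct = {a.rule.name for a in cross}
    if len(distinct) < 2:
        return False, cross
    aglycone_mzs = [m for ref in AGLYCONES
                    for m in (ref.even_mz, ref.radical_mz) if m is not None]
    for a in losses:
        if a.rule.category == "glycosyl" and any(abs(a.to_mz - m) <= tol for m in aglycone_mzs):
            return False, cross
    return True, cross


# ---------------------------------------------------------------------------
# loss-chain search
# ---------------------------------------------------------------------------

def _best_loss_chain(
    spectrum: MsmsSpectrum,
    losses: Sequence[LossAssignment],
    diagnostic_mzs: Sequence[float],
    tol: float,
    max_depth: int = 5,
) -> list[LossAssignment]:
    """Depth-first search for the best loss chain starting at the precursor.

    Larger-mass rules are tried first at each branch, each peak is consumed at
    most once, and among maximal chains the one terminating at a recognized
    diagnostic/aglycone ion wins, then the one explaining the most intensity.
    """
    by_parent: dict[float, list[LossAssignment]] = {}
    for a in losses:
        by_parent.setdefault(round(a.from_mz, 6), []).append(a)
    for lst in by_parent.values():
        lst.sort(key=lambda a: -a.rule.exact_mass)
    intensity = {round(p.mz, 6): p.intensity for p in spectrum.peaks}

    best: list[LossAssignment] = []
    best_key: tuple = (-1, -1.0)

    def walk(node: float, chain: list[LossAssignment], used: set[float]) -> None:
        nonlocal best, best_key
        children = [a for a in by_parent.get(round(node, 6), ())
                    if round(a.to_mz, 6) not in used]
        if not children or len(chain) >= max_depth:
            if chain:
                ends_at_diag = int(any(abs(chain[-1].to_mz - m) <= tol
                                       for m in diagnostic_mzs))
                explained = sum(intensity.get(round(a.to_mz, 6), 0.0) for a in chain)
                key = (ends_at_diag, explained)
                if key > best_key:
                    best, best_key = list(chain), key
            return
        for a in children:
            chain.append(a)
            used.add(round(a.to_mz, 6))
            walk(a.to_mz, chain, used)
            used.discard(round(a.to_mz, 6))
            chain.pop()

    walk(spectrum.precursor_mz, [], set())
    return best


def _decomposes_into_glycosyls(residual: float, tol: float, max_residues: int = 4) -> bool:
    """Can ``residual`` Da be written as a sum of 1..4 dehydrated sugar residues?"""
    masses = list(_GLYCOSYL_RESIDUES.values())
    for k in range(1, max_residues + 1):
        for combo in itertools.combinations_with_replacement(masses, k):
            if abs(residual - sum(combo)) <= tol * k:
                return True
    return False


# ---------------------------------------------------------------------------
# classification cascade
# ---------------------------------------------------------------------------

def classify_compound(
    spectrum: MsmsSpectrum,
    precursor_formula: Optional[ElementalFormula | str] = None,
    *,
    tol: float = DEFAULT_FRAGMENT_TOL,
    intensity_floor: float = DEFAULT_INTENSITY_FLOOR,
    rules: Sequence[NeutralLossRule] = DEFAULT_LOSS_RULES,
) -> AnnotationResult:
    """Call the compound class of one MS/MS spectrum from its fragment evidence.

    The cascade, in order of priority: amino acid (needs an N-containing
    precursor formula), phenolic acid/quinate ester, the flavan-3-ol family
    (with proanthocyanidin-dimer and galloylation sub-calls), flavone
    C-glycoside, acylated flavonol glycoside, flavonol O-glycoside, saccharide,
    and finally unclassified. The returned score is the fraction of total
    fragment intensity explained by the chosen loss chain, diagnostic ions and
    aglycone ions.
    """
    if not spectrum.peaks:
        raise ValueError("cannot classify an empty spectrum")
    if isinstance(precursor_formula, str):
        precursor_formula = parse_formula(precursor_formula)

    peaks = spectrum.above_floor(intensity_floor)
    working = MsmsSpectrum(spectrum.precursor_mz, peaks, rt=spectrum.rt,
                           sample_id=spectrum.sample_id)
    losses = detect_neutral_losses(working, rules, tol)
    aglycone = identify_aglycone(working, tol, intensity_floor=0.0)
    is_c_glycoside, cross_evidence = detect_c_glycoside(working, tol,
                                                        intensity_floor=0.0,
                                                        losses=losses)

    def has_ion(mz: float) -> Optional[Peak]:
        return _find_peak(peaks, mz, tol)

    diagnostic_hits: list[tuple[str, float, Peak]] = []
    for diag in DIAGNOSTIC_IONS:
        p = has_ion(diag.mz)
        if p is not None:
            diagnostic_hits.append((diag.name, diag.mz, p))

    flags: dict = {}
    prec = working.precursor_mz

    gallate_mz = _DIAG_BY_NAME["gallate"].mz
    quinate_mz = _DIAG_BY_NAME["quinate"].mz
    a_ring = _DIAG_BY_NAME["flavanol A-ring"].mz
    rda_pair = (_DIAG_BY_NAME["RDA 137"].mz, _DIAG_BY_NAME["RDA 151"].mz)
    methylgallate_rad = _DIAG_BY_NAME["methylgallate radical"].mz

    compound_class = "unclassified"
    position = "indeterminate"
    aglycone_name: Optional[str] = None

    precursor_losses = [a for a in losses if a.from_precursor]
    acyl_precursor = [a for a in precursor_losses if a.rule.category == "acyl"]
    acyl_names = {a.rule.name for a in acyl_precursor}

    if precursor_formula is not None and precursor_formula["N"] > 0 \
            and rdb(precursor_formula) < 4:
        # non-aromatic N compound (e.g. a free amino acid such as theanine)
        compound_class = "amino acid"
    elif abs(prec - quinate_mz) <= tol or abs(prec - gallate_mz) <= tol \
            or (prec < 400.0 and has_ion(quinate_mz) is not None):
        # the quinate-release route is limited to small precursors (caffeoyl/
        # coumaroyl quinic acids, theogallin); large glycosides can show
        # near-isobaric fragments in the 191 region
        # quinic/gallic acid themselves, or esters releasing the quinate ion
        compound_class = "phenolic acid/quinate ester"
    elif has_ion(a_ring) is not None or (has_ion(rda_pair[0]) and has_ion(rda_pair[1])):
        # quinone-methide fission of a dimer releases a genuine flavan-3-ol
        # monomer ion whose complement is the residual (epi)catechin /
        # (epi)gallocatechin unit (288.0634 / 304.0583 Da)
        monomer_mzs = (deprotonated_mz("C15H14O5"), deprotonated_mz("C15H14O6"),
                       deprotonated_mz("C15H14O7"))
        monomer_qm = any(
            abs(p.mz - m) <= tol and any(abs(prec - p.mz - x) <= 0.03
                                         for x in (288.0634, 304.0583))
            for m in monomer_mzs for p in peaks)
        hrf_loss = any(a.rule.name == "A-ring (HRF)" and a.from_precursor
                       for a in losses)
        # an acyl loss stripping the galloyl/methylgalloyl ester must leave an
        # intact flavanol core (>200 Da), not a low-mass ring fragment
        galloylated = (
            any(a.rule.name in _GALLOYLATION_LOSSES and a.to_mz >= 200.0
                for a in precursor_losses)
            or has_ion(gallate_mz) is not None
            or has_ion(methylgallate_rad) is not None)
        if monomer_qm and hrf_loss:
            compound_class = "proanthocyanidin dimer"
        elif galloylated:
            compound_class = "galloylated flavan-3-ol"
        else:
            compound_class = "flavan-3-ol"
    elif is_c_glycoside:
        compound_class = "flavone C-glycoside"
        position = "C-C"
        aglycone_name = aglycone.name if aglycone else None
    elif ({"coumaroyl", "coumaric acid"} <= acyl_names) or (
            aglycone is not None and any(
                _decomposes_into_glycosyls(a.to_mz - aglycone.reference.even_mz, 0.02)
                for a in acyl_precursor)):
        # a lone acyl loss only counts when stripping it leaves a plausible
        # glycoside ion (product − aglycone = sum of sugar residues)
        compound_class = "acylated flavonol glycoside"
        flags["acyl_acid_pair"] = {"coumaroyl", "coumaric acid"} <= acyl_names
        if flags["acyl_acid_pair"]:
            # acid and acid-H2O losses together point to acylation on the
            # sugar directly bound to the aglycone; recorded as evidence only
            flags["acyl_on_inner_sugar_evidence"] = True
        if aglycone:
            aglycone_name = aglycone.name
            position = aglycone.evidence
    elif aglycone and (
            any(a.rule.category == "glycosyl" for a in losses)
            or _decomposes_into_glycosyls(prec - aglycone.reference.even_mz, 0.01)):
        compound_class = "flavonol O-glycoside"
        aglycone_name = aglycone.name
        position = aglycone.evidence
    else:
        aromatic = aglycone is not None or any(
            has_ion(d.mz) for d in _AROMATIC_DIAGNOSTICS)
        sugarlike = any(a.rule.category in ("glycosyl", "ring-fission")
                        for a in losses)
        if sugarlike and not aromatic:
            compound_class = "saccharide"

    if compound_class in ("flavonol O-glycoside", "acylated flavonol glycoside") \
            and aglycone is not None:
        aglycone_name = aglycone.name
        position = aglycone.evidence

    diag_mzs = [d.mz for d in DIAGNOSTIC_IONS]
    diag_mzs += [m for ref in AGLYCONES for m in (ref.even_mz, ref.radical_mz)
                 if m is not None]
    chain = _best_loss_chain(working, losses, diag_mzs, tol)

    explained: set[float] = set()
    for a in chain:
        explained.add(round(a.to_mz, 6))
    for _, _, p in diagnostic_hits:
        explained.add(round(p.mz, 6))
    if aglycone:
        for p in (aglycone.even_peak, aglycone.radical_peak):
            if p is not None:
                explained.add(round(p.mz, 6))
    if _find_peak(peaks, prec, tol):
        explained.add(round(_find_peak(peaks, prec, tol).mz, 6))
    total = sum(p.intensity for p in peaks)
    score = sum(p.intensity for p in peaks if round(p.mz, 6) in explained) / total \
        if total > 0 else 0.0

    return AnnotationResult(
        compound_class=compound_class,
        aglycone=aglycone_name,
        loss_chain=[(a.rule.name, a.from_mz, a.to_mz, a.delta) for a in chain],
        diagnostic_hits=diagnostic_hits,
        position_evidence=position,
        score=min(score, 1.0),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# library matching and summaries
# ---------------------------------------------------------------------------

def annotate_library(
    spectra: Sequence[MsmsSpectrum],
    library: Optional[Sequence[CompoundLibraryEntry]] = None,
    precursor_tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM,
    rt_tol_min: float = 0.5,
    *,
    fragment_tol: float = DEFAULT_FRAGMENT_TOL,
) -> pd.DataFrame:
    """Annotate spectra against a compound library, plus de novo class calls.

    The best library match minimizes |precursor ppm error|, with retention-time
    proximity (within ``rt_tol_min``) breaking near-ties. Unmatched spectra are
    retained with the de novo classification only.
    """
    if library is None:
        library = load_compound_library()
    if not library:
        raise ValueError("library must be non-empty")
    rows = []
    for i, spectrum in enumerate(spectra):
        candidates = []
        for entry in library:
            ppm = ppm_error(spectrum.precursor_mz, entry.calc_mz, decimals=None)
            if abs(ppm) <= precursor_tol_ppm:
                if spectrum.rt is not None:
                    dt = abs(spectrum.rt - entry.rt)
                    rt_pen = dt if dt <= rt_tol_min else float("inf")
                else:
                    rt_pen = 0.0
                candidates.append((abs(ppm), rt_pen, entry, ppm))
        candidates = [c for c in candidates if c[1] != float("inf")] or candidates
        match = min(candidates, key=lambda c: (round(c[0], 1), c[1])) if candidates else None
        entry = match[2] if match else None
        result = classify_compound(spectrum,
                                   precursor_formula=entry.formula if entry else None,
                                   tol=fragment_tol)
        rows.append({
            "peak_id": spectrum.sample_id or f"spectrum_{i}",
            "precursor_mz": round_half_up(spectrum.precursor_mz, 4),
            "matched_peak_no": entry.peak_no if entry else None,
            "matched_name": entry.name if entry else None,
            "formula": entry.formula.hill() if entry else None,
            "calc_mz": round_half_up(entry.calc_mz, 4) if entry else None,
            "ppm": round_half_up(match[3], 1) if match else None,
            "rdb": rdb(entry.formula) if entry else None,
            "class": result.compound_class,
            "aglycone": result.aglycone,
            "position_evidence": result.position_evidence,
            "loss_chain": ";".join(
                f"{name}:{f:.4f}->{t:.4f}" for name, f, t, _ in result.loss_chain),
            "score": round(result.score, 4),
        })
    return pd.DataFrame(rows)


def class_relative_abundance(
    annotations,
    *,
    class_column: str = "class",
    abundance_column: str = "abundance",
) -> dict[str, float]:
    """Percent of summed abundance per compound class.

    ``annotations`` is either a DataFrame with class/abundance columns or an
    iterable of ``(class_label, abundance)`` pairs. Percentages sum to 100.
    """
    if isinstance(annotations, pd.DataFrame):
        pairs = list(zip(annotations[class_column], annotations[abundance_column]))
    else:
        pairs = [(c, a) for c, a in annotations]
    totals: dict[str, float] = {}
    for label, abundance in pairs:
        if abundance < 0:
            raise ValueError("abundances must be non-negative")
        totals[label] = totals.get(label, 0.0) + float(abundance)
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("total abundance is zero")
    return {label: 100.0 * v / grand for label, v in totals.items()}
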