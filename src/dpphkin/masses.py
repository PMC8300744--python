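"""Exact-mass annotation of DPPH*-antioxidant reaction products.

Phenolic antioxidants oxidised by DPPH* show a small, enumerable product
space in negative-mode ESI: the intact monomer, its quinone (-2H), C-C/C-O
coupled dimers (2M - 2H, with deeper dehydrogenation when methanol adds),
covalent DPPH coupling adducts, and methanol / formic-acid adducts picked
up from solvent and eluent.  This module enumerates those candidates from
an elemental formula, computes theoretical m/z for the two negative-mode
ion types ([M-H]- and the radical anion [M]*-), and matches observed m/z
lists within a ppm tolerance.

Monoisotopic atomic masses come from the NIST table shipped with
pyteomics; the electron mass is included in all anion m/z values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "MolecularComposition",
    "CandidateProduct",
    "MatchResult",
    "FormulaError",
    "ELECTRON_MASS",
    "DPPH_FORMULA",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "enumerate_products",
    "annotate_observed",
]

#: electron rest mass, Da (CODATA)
ELECTRON_MASS = 0.000548579909

#: elemental formula of the DPPH radical
DPPH_FORMULA = "C18H12N5O6"

#: elements accepted by the parser
SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "S", "P", "Na", "K", "Cl")

_MONO = {el: _pmass.nist_mass[el][0][0] for el in SUPPORTED_ELEMENTS}
_H_MASS = _MONO["H"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: default matching tolerance, ppm
DEFAULT_TOL_PPM = 5.0


class FormulaError(ValueError):
    """Malformed formula string or unsupported element."""


@dataclass(frozen=True)
class MolecularComposition:
    """Immutable element -> count map supporting formula arithmetic."""

    counts: tuple  # sorted tuple of (element, count)

    @classmethod
    def from_dict(cls, d: Dict[str, int]) -> "MolecularComposition":
        clean = {el: int(n) for el, n in d.items() if n != 0}
        if not clean:
            raise FormulaError("composition must contain at least one atom")
        for el, n in clean.items():
            if el not in _MONO:
                raise FormulaError(f"unsupported element {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
        return cls(counts=tuple(sorted(clean.items())))

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "MolecularComposition") -> "MolecularComposition":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return MolecularComposition.from_dict(d)

    def scale(self, factor: int) -> "MolecularComposition":
        return MolecularComposition.from_dict(
            {el: n * factor for el, n in self.counts}
        )

    def remove_h(self, n: int) -> Optional["MolecularComposition"]:
        """Composition with n hydrogens removed, or None if impossible."""
        d = self.as_dict()
        if d.get("H", 0) < n:
            return None
        d["H"] -= n
        try:
            return MolecularComposition.from_dict(d)
        except FormulaError:
            return None

    def hill_formula(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        d = self.as_dict()
        parts = []
        for el in ("C", "H"):
            if el in d:
                parts.append(f"{el}{d[el] if d[el] != 1 else ''}")
        for el in sorted(k for k in d if k not in ("C", "H")):
            parts.append(f"{el}{d[el] if d[el] != 1 else ''}")
        return "".join(parts)


@dataclass(frozen=True)
class CandidateProduct:
    """An enumerated product: composition plus a composable provenance label."""

    composition: MolecularComposition
    label: str

    @property
    def mz_deprotonated(self) -> Optional[float]:
        try:
            return ion_mz(self.composition, "deprotonated")
        except FormulaError:
            return None

    @property
    def mz_radical_anion(self) -> float:
        return ion_mz(self.composition, "radical_anion")


@dataclass(frozen=True)
class MatchResult:
    """Best candidate for one observed m/z, or unmatched."""

    observed_mz: float
    candidate: Optional[CandidateProduct]
    ion_type: Optional[str]
    theoretical_mz: Optional[float]
    ppm_error: Optional[float]

    @property
    def matched(self) -> bool:
        return self.candidate is not None


def parse_formula(text: str) -> MolecularComposition:
    """Parse a plain formula string like ``C7H6O5`` (implicit 1 allowed)."""
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    pos = 0
    d: Dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in _MONO:
            raise FormulaError(f"unsupported element {el!r} in {text!r}")
        d[el] = d.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
        if pos == len(text):
            break
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return MolecularComposition.from_dict(d)


def monoisotopic_mass(comp: MolecularComposition) -> float:
    """Neutral monoisotopic mass in Da (most abundant isotope per element)."""
    return sum(_MONO[el] * n for el, n in comp.counts)


def ion_mz(comp: MolecularComposition, ion_type: str) -> float:
    """Theoretical m/z of a singly charged negative ion.

    ``deprotonated``: [M-H]- = M - m_H + m_e (requires at least one H);
    ``radical_anion``: [M]*- = M + m_e.
    """
    m = monoisotopic_mass(comp)
    if ion_type == "deprotonated":
        if comp.as_dict().get("H", 0) < 1:
            raise FormulaError("cannot deprotonate an H-free composition")
        return m - _H_MASS + ELECTRON_MASS
    if ion_type == "radical_anion":
        return m + ELECTRON_MASS
    raise ValueError(f"unknown ion type {ion_type!r}")


_DPPH = None


def _dpph_composition() -> MolecularComposition:
    global _DPPH
    if _DPPH is None:
        _DPPH = parse_formula(DPPH_FORMULA)
    return _DPPH


_METHANOL = MolecularComposition.from_dict({"C": 1, "H": 4, "O": 1})
_FORMIC = MolecularComposition.from_dict({"C": 1, "H": 2, "O": 2})


def enumerate_products(antioxidant: MolecularComposition) -> List[CandidateProduct]:
    """Enumerate candidate reaction products of one antioxidant.

    Base species: monomer M, quinone M-2H, dimers 2M-2H and 2M-4H.
    Each base may couple with DPPH at hydrogen offsets -1, 0, +1 relative
    to the plain sum (radical recombination vs H-transfer pathways differ
    by H2).  Any species may additionally pick up methanol (+CH4O) and/or
    formic acid (+CH2O2); the deeper 4H dimer dehydrogenation is only kept
    in methanol-adduct form.  Candidates are de-duplicated by composition,
    keeping the shortest provenance label.
    """
    if antioxidant.as_dict().get("H", 0) < 2:
        raise FormulaError("antioxidant needs >= 2 hydrogens to enumerate")
    dpph = _dpph_composition()

    bases: List[CandidateProduct] = [CandidateProduct(antioxidant, "monomer")]
    q = antioxidant.remove_h(2)
    if q is not None:
        bases.append(CandidateProduct(q, "quinone"))
    dimer2 = antioxidant.scale(2).remove_h(2)
    if dimer2 is not None:
        bases.append(CandidateProduct(dimer2, "dimer"))
    dimer4 = antioxidant.scale(2).remove_h(4)  # only emitted with +CH3OH

    coupled: List[CandidateProduct] = []
    for base in bases:
        combo = base.composition + dpph
        for dh, tag in ((1, "+DPPH-H"), (0, "+DPPH"), (-1, "+DPPH+H")):
            c = combo.remove_h(dh) if dh > 0 else (
                combo if dh == 0 else combo + MolecularComposition.from_dict({"H": 1})
            )
            if c is not None:
                coupled.append(CandidateProduct(c, base.label + tag))

    solvated: List[CandidateProduct] = []
    for cand in bases + coupled:
        solvated.append(CandidateProduct(cand.composition + _METHANOL,
                                         cand.label + "+CH3OH"))
        solvated.append(CandidateProduct(cand.composition + _FORMIC,
                                         cand.label + "+HCOOH"))
        solvated.append(CandidateProduct(cand.composition + _METHANOL + _FORMIC,
                                         cand.label + "+CH3OH+HCOOH"))
    if dimer4 is not None:
        solvated.append(CandidateProduct(dimer4 + _METHANOL, "dimer-2H+CH3OH"))

    # de-duplicate by composition, shortest label wins
    seen: Dict[tuple, CandidateProduct] = {}
    for cand in bases + coupled + solvated:
        key = cand.composition.counts
        if key not in seen or len(cand.label) < len(seen[key].label):
            seen[key] = cand
    return list(seen.values())


def annotate_observed(
    observed_mz: Sequence[float],
    candidates: Sequence[CandidateProduct],
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> List[MatchResult]:
    """Match each observed m/z to its minimum-|ppm| candidate.

    Both negative-mode ion types are tried for every candidate; an observed
    value with no candidate inside ``tol_ppm`` is flagged unmatched.
    """
    if not tol_ppm > 0:
        raise ValueError("tol_ppm must be positive")
    results = []
    for mz in observed_mz:
        best = None
        for cand in candidates:
            for ion in ("deprotonated", "radical_anion"):
                try:
                    theo = ion_mz(cand.composition, ion)
                except FormulaError:
                    continue
                ppm = (mz - theo) / theo * 1e6
                if abs(ppm) <= tol_ppm and (best is None or abs(ppm) < abs(best[2])):
                    best = (cand, ion, ppm, theo)
        if best is None:
            results.append(MatchResult(mz, None, None, None, None))
        else:
            cand, ion, ppm, theo = best
            results.append(MatchResult(mz, cand, ion, theo, ppm))
    return results
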