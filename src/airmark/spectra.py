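"""Accurate-mass EI spectra and the base-peak-robust similarity score.

Low-mass volatiles fragment into a small set of CHO(N,S) ions whose exact
masses cluster around m/z 40-45; alignment across samples therefore works on
centroided accurate-mass spectra truncated to the seven most intense ions and
normalized to the base peak.  The similarity score is a weighted sum of three
cosine (normalized dot-product) terms: the full spectra, the spectra with the
first spectrum's base peak removed, and the spectra with the second spectrum's
base peak removed.  Removing each base peak in turn makes the score robust to
the rank swaps between top ions that occur near the detection limit, where the
base peak is no longer a reliable anchor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "Spectrum",
    "normalize_spectrum",
    "match_ions",
    "cosine_term",
    "similarity_score",
    "formula_to_mz",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "MAX_IONS",
]

#: Monoisotopic atomic masses (Da) for the elements found in breath volatiles.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

ELECTRON_MASS = 0.000549  # Da

#: Ions retained per spectrum; the contribution of lower-rank ions to the
#: similarity score is negligible for small VOCs.
MAX_IONS = 7

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_to_mz(formula: str, charge: int = 1) -> float:
    """Exact m/z of a singly charged cation from its elemental formula.

    Sums monoisotopic atomic masses and subtracts one electron mass.  Formulas
    use Hill-like notation without the charge sign, e.g. ``"C2H3O"`` for the
    acetyl cation (43.018 Th).

    Raises
    ------
    ValueError
        If the formula contains an element outside C/H/N/O/S, cannot be
        parsed, or ``charge`` is not +1.
    """
    if charge != 1:
        raise ValueError("only singly charged cations are supported")
    pos = 0
    mass = 0.0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        element, count = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        mass += MONOISOTOPIC_MASS[element] * (int(count) if count else 1)
        pos = m.end()
    if pos != len(formula) or pos == 0:
        raise ValueError(f"cannot parse formula {formula!r}")
    return mass - charge * ELECTRON_MASS


@dataclass(frozen=True)
class Spectrum:
    """A centroided spectrum as (m/z, relative intensity) pairs.

    Ions are sorted by descending relative intensity, ties by ascending m/z,
    so ``ions[0]`` is the base peak (relative intensity 1.0 for a spectrum
    built through :func:`normalize_spectrum`).  At most :data:`MAX_IONS` ions
    are kept.  Reduced spectra (a base peak removed) reuse this class and may
    be empty or lack an ion at 1.0.
    """

    ions: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.ions)

    @property
    def base_peak_mz(self) -> float:
        if not self.ions:
            raise ValueError("empty spectrum has no base peak")
        return self.ions[0][0]

    def without_index(self, index: int | None) -> "Spectrum":
        """Copy of the spectrum with the ion at ``index`` removed."""
        if index is None:
            return self
        return Spectrum(self.ions[:index] + self.ions[index + 1:])


def _sort_ions(ions: Iterable[tuple[float, float]]) -> tuple[tuple[float, float], ...]:
    return tuple(sorted(ions, key=lambda ion: (-ion[1], ion[0])))


def normalize_spectrum(raw: Sequence[tuple[float, float]]) -> Spectrum:
    """Build a :class:`Spectrum` from (m/z, absolute intensity) pairs.

    The seven most intense ions are retained and intensities are divided by
    the maximum.  When two ions tie at the maximum intensity the lower-m/z ion
    becomes the base peak (deterministic tie break).

    Raises
    ------
    ValueError
        If no ion has positive intensity.
    """
    positive = [(mz, inten) for mz, inten in raw if inten > 0]
    if not positive:
        raise ValueError("spectrum has no ion with positive intensity")
    ordered = _sort_ions(positive)[:MAX_IONS]
    base_intensity = ordered[0][1]
    return Spectrum(tuple((mz, inten / base_intensity) for mz, inten in ordered))


def match_ions(
    u: Spectrum, v: Spectrum, mz_tol: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one pairing of ions closer than ``mz_tol`` in m/z.

    Candidate pairs are sorted by ascending mass difference (ties broken on
    the smaller then larger m/z of the pair, which keeps the pairing symmetric
    in its arguments) and accepted while both ions are unmatched.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    candidates = []
    for i, (umz, _) in enumerate(u.ions):
        for j, (vmz, _) in enumerate(v.ions):
            delta = abs(umz - vmz)
            if delta < mz_tol:
                candidates.append((delta, min(umz, vmz), max(umz, vmz), i, j))
    candidates.sort()
    used_u: set[int] = set()
    used_v: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, i, j in candidates:
        if i not in used_u and j not in used_v:
            used_u.add(i)
            used_v.add(j)
            pairs.append((i, j))
    return pairs


def cosine_term(u: Spectrum, v: Spectrum, matching: Sequence[tuple[int, int]]) -> float:
    """Normalized dot product over matched ions.

    Unmatched ions contribute to the Euclidean norms but zero to the dot
    product.  Conventions for reduced spectra: both empty -> 1.0 (removing the
    only ion from identical single-ion spectra must not break self-similarity);
    exactly one empty -> 0.0.
    """
    if not u.ions and not v.ions:
        return 1.0
    if not u.ions or not v.ions:
        return 0.0
    # summing in index order keeps the dot product bitwise equal to the norms
    # for identical spectra, so cos(u, u) is exactly 1
    dot = sum(u.ions[i][1] * v.ions[j][1] for i, j in sorted(matching))
    norm_sq_u = sum(inten * inten for _, inten in u.ions)
    norm_sq_v = sum(inten * inten for _, inten in v.ions)
    # sqrt of the product (not product of sqrts) keeps cos(u, u) == 1 exactly
    return min(dot / (norm_sq_u * norm_sq_v) ** 0.5, 1.0)


def _matched_partner(matching: Sequence[tuple[int, int]], *, u_index: int | None = None,
                     v_index: int | None = None) -> int | None:
    if u_index is not None:
        for i, j in matching:
            if i == u_index:
                return j
    if v_index is not None:
        for i, j in matching:
            if j == v_index:
                return i
    return None


def similarity_score(u: Spectrum, v: Spectrum, mz_tol: float) -> float:
    """Base-peak-robust spectral similarity in [0, 1].

    ``0.5 * cos(U, V) + 0.25 * cos(U', V') + 0.25 * cos(U'', V'')`` where the
    primed spectra have u's base peak removed (from u, and from v the ion
    matched to it, if any) and the double-primed spectra analogously remove
    v's base peak.  Because the two reduced terms swap roles under argument
    exchange, the score is symmetric; identical spectra score exactly 1.
    """
    matching = match_ions(u, v, mz_tol)
    full = cosine_term(u, v, matching)

    u_base = 0 if u.ions else None
    v_base = 0 if v.ions else None

    u1 = u.without_index(u_base)
    v1 = v.without_index(_matched_partner(matching, u_index=u_base) if u_base is not None else None)
    reduced_u = cosine_term(u1, v1, match_ions(u1, v1, mz_tol))

    u2 = u.without_index(_matched_partner(matching, v_index=v_base) if v_base is not None else None)
    v2 = v.without_index(v_base)
    reduced_v = cosine_term(u2, v2, match_ions(u2, v2, mz_tol))

    return 0.5 * full + 0.25 * reduced_u + 0.25 * reduced_v
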