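"""Fatty acids, triacylglycerol (TAG) species, and partition-number bookkeeping.

A TAG species is an unordered triple of acyl chains on a glycerol backbone.
Reversed-phase C18 chromatography elutes TAG species roughly in order of the
partition number

    PN = CN - 2 * ND

where CN is the total acyl carbon number and ND the total number of double
bonds.  This module computes PN and molar masses, enumerates plausible TAG
species from a bulk fatty-acid composition, and annotates chromatogram peaks
by PN group in elution order.

Positional (sn-1/2/3) isomers are deliberately not distinguished: every
computation here is invariant under permutation of the three acyls.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass, field, replace

from .constants import GLYCEROL, WATER, fatty_acid_mass
from .errors import ValidationError

__all__ = [
    "FattyAcid",
    "TAGSpecies",
    "OilComposition",
    "SpeciesCandidate",
    "FATTY_ACIDS",
    "OIL_COMPOSITIONS",
    "TAG_PROFILES",
    "fatty_acid",
    "tag_from_labels",
    "parse_tag_label",
    "partition_number",
    "tag_molar_mass",
    "mean_oil_molar_mass",
    "enumerate_plausible_species",
    "annotate_peaks",
]


@dataclass(frozen=True)
class FattyAcid:
    """A fatty acid identified by chain length and double-bond count.

    ``code`` follows lipid shorthand (e.g. ``"C18:2 n-6"``); ``label`` is the
    one-to-three letter abbreviation used in TAG species names (e.g. ``"L"``).
    ``molar_mass`` defaults to the CnH(2n-2d)O2 atomic-mass sum and is
    validated to stay within 1 g/mol of it.
    """

    code: str
    label: str
    carbons: int
    double_bonds: int
    conjugated: bool = False
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValidationError(f"{self.code}: need at least 2 carbons, got {self.carbons}")
        if self.double_bonds < 0 or self.double_bonds >= self.carbons / 2:
            raise ValidationError(
                f"{self.code}: double_bonds must satisfy 0 <= d < carbons/2"
            )
        formula = fatty_acid_mass(self.carbons, self.double_bonds)
        if self.molar_mass is None:
            object.__setattr__(self, "molar_mass", formula)
        elif not self.molar_mass > 0 or abs(self.molar_mass - formula) > 1.0:
            raise ValidationError(
                f"{self.code}: molar_mass {self.molar_mass} is more than 1 g/mol away "
                f"from the CnH(2n-2d)O2 sum {formula:.3f}"
            )


#: Registry of the fatty acids that occur in the supported oils, plus the
#: internal standard's undecanoic acid.  Keyed by code.
FATTY_ACIDS: dict[str, FattyAcid] = {
    fa.code: fa
    for fa in [
        FattyAcid("C11:0", "U", 11, 0),
        FattyAcid("C16:0", "P", 16, 0),
        FattyAcid("C18:0", "S", 18, 0),
        FattyAcid("C18:1 n-9", "O", 18, 1),
        FattyAcid("C18:1 n-7", "V", 18, 1),
        FattyAcid("C18:2t", "Lt", 18, 2),
        FattyAcid("C18:2 n-6", "L", 18, 2),
        FattyAcid("C18:3 n-6", "gLn", 18, 3),
        FattyAcid("C18:3 n-3", "Ln", 18, 3),
        FattyAcid("C18:3 n-5", "CLn", 18, 3, conjugated=True),
    ]
}

_BY_LABEL: dict[str, FattyAcid] = {fa.label: fa for fa in FATTY_ACIDS.values()}


def fatty_acid(key: str) -> FattyAcid:
    """Look up a registry fatty acid by code or label."""
    if key in FATTY_ACIDS:
        return FATTY_ACIDS[key]
    if key in _BY_LABEL:
        return _BY_LABEL[key]
    raise ValidationError(f"unknown fatty acid {key!r}")


def _canonical_acyls(acyls: tuple[FattyAcid, ...]) -> tuple[FattyAcid, ...]:
    # Sort so that the label and all derived quantities are permutation
    # invariant: most unsaturated first, then longest, then by label.
    return tuple(
        sorted(acyls, key=lambda fa: (-fa.double_bonds, -fa.carbons, fa.label))
    )


@dataclass(frozen=True)
class TAGSpecies:
    """An unordered triple of acyl chains esterified to glycerol."""

    acyls: tuple[FattyAcid, ...]

    def __post_init__(self) -> None:
        if len(self.acyls) != 3:
            raise ValidationError(
                f"a TAG species has exactly 3 acyl chains, got {len(self.acyls)}"
            )
        object.__setattr__(self, "acyls", _canonical_acyls(tuple(self.acyls)))

    @property
    def cn(self) -> int:
        """Total carbon number CN (acyl carbons only)."""
        return sum(fa.carbons for fa in self.acyls)

    @property
    def nd(self) -> int:
        """Total double-bond number ND."""
        return sum(fa.double_bonds for fa in self.acyls)

    @property
    def pn(self) -> int:
        """Partition number, PN = CN - 2*ND."""
        return self.cn - 2 * self.nd

    @property
    def molar_mass(self) -> float:
        """Molar mass from 3 esterifications: sum(FFA) + glycerol - 3 H2O."""
        return sum(fa.molar_mass for fa in self.acyls) + GLYCEROL - 3 * WATER

    @property
    def label(self) -> str:
        return "-".join(fa.label for fa in self.acyls)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def tag_from_labels(*labels: str) -> TAGSpecies:
    """Build a TAG species from three fatty-acid labels, e.g. ``("CLn","CLn","O")``."""
    return TAGSpecies(tuple(fatty_acid(lb) for lb in labels))


_PAREN = re.compile(r"\([^)]*\)")


def parse_tag_label(label: str) -> TAGSpecies:
    """Parse a species label such as ``"CLn-CLn-P"`` into a :class:`TAGSpecies`.

    Co-elution notation is tolerated: for ``"L-L-S/P-L-O"`` the first variant
    is parsed; a parenthesised alternative acyl as in ``"CLn-CLn-O(P)"`` is
    dropped.
    """
    first = _PAREN.sub("", label.split("/")[0].strip())
    parts = [p for p in first.split("-") if p]
    if len(parts) != 3:
        raise ValidationError(f"cannot parse TAG label {label!r}")
    return tag_from_labels(*parts)


def partition_number(species: TAGSpecies) -> int:
    """PN = CN - 2*ND for a valid 3-acyl species."""
    if not isinstance(species, TAGSpecies):
        raise ValidationError("partition_number expects a TAGSpecies")
    return species.pn


def tag_molar_mass(species: TAGSpecies) -> float:
    """Molar mass (g/mol) of a TAG: sum of acyl FFA masses + glycerol - 3 H2O."""
    if not isinstance(species, TAGSpecies):
        raise ValidationError("tag_molar_mass expects a TAGSpecies")
    return species.molar_mass


@dataclass(frozen=True)
class OilComposition:
    """Bulk fatty-acid composition of an oil as GC area percentages.

    ``entries`` pairs registry fatty acids with area %, ``unknown_percent``
    covers unidentified peaks.  The total must land in [98, 102] to absorb
    rounding in published tables.
    """

    name: str
    entries: tuple[tuple[FattyAcid, float], ...]
    unknown_percent: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if any(pct < 0 for _, pct in self.entries) or self.unknown_percent < 0:
            raise ValidationError(f"{self.name}: negative area percent")
        total = sum(pct for _, pct in self.entries) + self.unknown_percent
        if not 98.0 <= total <= 102.0:
            raise ValidationError(
                f"{self.name}: area percentages sum to {total:.1f}, outside [98, 102]"
            )

    @property
    def known_percent(self) -> float:
        return sum(pct for _, pct in self.entries)

    def mole_fractions(self) -> dict[FattyAcid, float]:
        """Known-acid area % renormalised to fractions summing to 1.

        GC-FID FAME area % is treated as acyl mole % — an excellent
        approximation for C16–C18 dominated oils.
        """
        known = self.known_percent
        if known <= 0:
            raise ValidationError(f"{self.name}: empty composition")
        return {fa: pct / known for fa, pct in self.entries if pct > 0}


def _comp(name: str, unknown: float, **area_by_label: float) -> OilComposition:
    entries = tuple(
        (fatty_acid(lbl), pct) for lbl, pct in area_by_label.items() if pct > 0
    )
    return OilComposition(name=name, entries=entries, unknown_percent=unknown)


#: Built-in bulk fatty-acid compositions (GC area %) of soybean oil (SBO),
#: pomegranate seed oil (PGO), their 1:1 physical blend (PHY) and the
#: enzymatically interesterified counterpart (IO).
OIL_COMPOSITIONS: dict[str, OilComposition] = {
    "SBO": _comp("SBO", 2.0, P=13.1, S=3.8, O=22.1, V=2.8, Lt=0.5, L=49.5,
                 gLn=0.6, Ln=5.5),
    "PGO": _comp("PGO", 1.2, P=4.0, S=2.6, O=7.0, V=1.1, Lt=0.9, L=8.5,
                 CLn=74.7),
    "PHY": _comp("PHY", 1.8, P=9.8, S=4.0, O=18.1, V=2.4, Lt=0.6, L=35.1,
                 gLn=0.3, Ln=3.4, CLn=24.7),
    "IO": _comp("IO", 1.9, P=8.8, S=3.7, O=16.7, V=2.7, Lt=0.8, L=32.9,
                gLn=0.3, Ln=3.0, CLn=29.2),
}

#: Published TAG-species profiles (HPLC area %) per oil, keyed by the species
#: label as printed; used as annotation fixtures and as default mass
#: fractions in the synthetic generator.  "Unknown" collects unassigned area.
TAG_PROFILES: dict[str, dict[str, float]] = {
    "SBO": {
        "L-L-Ln": 6.0, "L-L-L": 24.5, "O-L-Ln": 2.8, "L-L-O": 21.4,
        "P-L-L": 15.2, "L-O-O": 6.8, "L-L-S/P-L-O": 12.7, "S-L-O": 4.2,
        "Unknown": 6.4,
    },
    "PGO": {
        "CLn-CLn-CLn": 67.8, "CLn-CLn-L": 7.9, "CLn-CLn-O(P)": 12.1,
        "Unknown": 12.2,
    },
    "PHY": {
        "CLn-CLn-CLn": 24.8, "CLn-CLn-L": 3.0, "L-L-Ln": 2.7,
        "CLn-CLn-O(P)": 4.7, "L-L-L": 12.9, "O-L-Ln": 1.7, "L-L-O": 13.2,
        "P-L-L": 9.0, "L-O-O": 4.8, "L-L-S/P-L-O": 8.6, "S-L-O": 3.0,
        "Unknown": 11.7,
    },
    "IO": {
        "CLn-CLn-CLn/CLn-CLn-Ln": 3.4, "CLn-CLn-L/CLn-Ln-L": 18.0,
        "L-L-Ln/L-L-CLn": 14.7, "CLn-CLn-O(P)/CLn-Ln-O(P)": 10.4,
        "L-L-L": 2.2, "O-L-Ln/O-L-CLn": 18.5, "L-L-O": 5.2, "P-L-L": 5.9,
        "L-O-O": 1.4, "L-L-S/P-L-O": 3.0, "Unknown": 17.2,
    },
}


def mean_oil_molar_mass(comp: OilComposition, min_coverage: float = 0.90) -> float:
    """Mean TAG molar mass (g/mol) of an oil from its fatty-acid composition.

    Area % over the known acids is renormalised and treated as acyl mole
    fraction; the mean TAG mass is then 3 x (mean acyl FFA mass) + glycerol
    - 3 x H2O.  Requires the identified acids to cover at least
    ``min_coverage`` of the total area.
    """
    total = comp.known_percent + comp.unknown_percent
    coverage = comp.known_percent / total if total > 0 else 0.0
    if coverage < min_coverage:
        raise ValidationError(
            f"{comp.name}: identified fatty acids cover only {coverage:.1%} of area "
            f"(unknown fraction {comp.unknown_percent:.1f}%); need >= {min_coverage:.0%}"
        )
    fractions = comp.mole_fractions()
    mean_ffa = sum(f * fa.molar_mass for fa, f in fractions.items())
    return 3 * mean_ffa + GLYCEROL - 3 * WATER


@dataclass(frozen=True)
class SpeciesCandidate:
    """A plausible TAG species with its estimated abundance.

    The abundance is the multinomial product of acyl mole fractions (random
    acyl distribution assumption) — a tie-breaking heuristic, not a
    prediction of the true TAG profile.
    """

    species: TAGSpecies
    abundance: float

    @property
    def pn(self) -> int:
        return self.species.pn


def enumerate_plausible_species(
    comp: OilComposition, min_abundance: float = 0.05
) -> list[SpeciesCandidate]:
    """All 3-multisets of fatty acids above ``min_abundance``, grouped by PN.

    Returns candidates sorted by PN ascending, then estimated abundance
    descending.  With k acids above the threshold the list has C(k+2, 3)
    entries.
    """
    if not 0 < min_abundance <= 1:
        raise ValidationError("min_abundance must be in (0, 1]")
    fractions = comp.mole_fractions()
    majors = [(fa, f) for fa, f in fractions.items() if f >= min_abundance]
    if not majors:
        raise ValidationError(
            f"{comp.name}: no fatty acid reaches abundance {min_abundance}"
        )
    out: list[SpeciesCandidate] = []
    for combo in itertools.combinations_with_replacement(majors, 3):
        acyls = tuple(fa for fa, _ in combo)
        mult = math.factorial(3)
        for _, count in itertools.groupby(acyls, key=lambda fa: fa.code):
            mult //= math.factorial(len(list(count)))
        abundance = mult * math.prod(f for _, f in combo)
        out.append(SpeciesCandidate(TAGSpecies(acyls), abundance))
    out.sort(key=lambda c: (c.pn, -c.abundance, c.species.label))
    return out


def annotate_peaks(peaks, candidates: list[SpeciesCandidate]):
    """Annotate chromatogram peaks with PN groups in elution order.

    On reversed-phase C18, PN increases with retention time, so PN groups are
    assigned to peaks one-to-one in elution order; within a group the most
    abundant candidate names the peak.  Peaks beyond the last PN group are
    labelled ``"Unknown"``; PN groups beyond the last peak are reported via a
    warning, not an error.

    ``peaks`` is an :class:`~lipolyzer.elsd.PeakTable`; a new table is
    returned, the input is not mutated.
    """
    from .elsd import Peak, PeakTable  # local import: elsd does not import us

    if not isinstance(peaks, PeakTable):
        raise ValidationError("annotate_peaks expects a PeakTable")
    rts = [p.retention_min for p in peaks.peaks]
    if rts != sorted(rts):
        raise ValidationError("peaks must be sorted by retention time")

    groups: list[list[SpeciesCandidate]] = []
    for _, grp in itertools.groupby(
        sorted(candidates, key=lambda c: (c.pn, -c.abundance)), key=lambda c: c.pn
    ):
        groups.append(list(grp))

    new_peaks = []
    for i, peak in enumerate(peaks.peaks):
        if i < len(groups):
            label = groups[i][0].species.label
        else:
            label = "Unknown"
        new_peaks.append(replace(peak, annotation=label))
    if len(groups) > len(peaks.peaks):
        leftover = [g[0].pn for g in groups[len(peaks.peaks):]]
        warnings.warn(
            f"{len(leftover)} PN group(s) without a matching peak: PN {leftover}",
            stacklevel=2,
        )
    return replace(peaks, peaks=tuple(new_peaks))
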