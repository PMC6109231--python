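"""Label-free quantification of proteins and complexes.

Two per-protein abundance measures are supported:

* NSAF — normalized spectral abundance factor, ``(SpC_i/L_i) / Σ_j (SpC_j/L_j)``
  where SpC is the spectral count and L the protein length in residues.
  NSAF values sum to 1 over the identified proteins.
* top-3 XIC — the mean of the three largest peptide peak areas of a protein
  (all available areas if fewer than three; 0 for none).

Complex abundance is the mean of a measure over ALL defined subunits of the
complex, with subunits that were not identified contributing zero.  That
zero-imputation rule makes complex abundance sensitive to coverage as well
as to per-protein intensity, which is the intended behaviour when ranking
candidate complexes by how visible they should be.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .complexome import ComplexRecord

__all__ = [
    "ProteinObservation",
    "nsaf",
    "top3_xic",
    "complex_abundance",
    "abundance_table",
    "quant_correlation",
    "stoichiometry_ratio",
]


@dataclass
class ProteinObservation:
    """One identified protein: length (aa), spectral count, peptide areas."""

    accession: str
    length: int
    spectral_count: int
    peptide_areas: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.accession}: length must be >= 1")
        if self.spectral_count < 0:
            raise ValueError(f"{self.accession}: spectral count must be >= 0")
        for a in self.peptide_areas:
            if not math.isfinite(a) or a < 0:
                raise ValueError(f"{self.accession}: peptide areas must be finite and >= 0")


def nsaf(observations: Sequence[ProteinObservation]) -> dict[str, float]:
    """Per-protein NSAF values; they sum to 1 over the input."""
    saf = {o.accession: o.spectral_count / o.length for o in observations}
    total = sum(saf.values())
    if total <= 0:
        raise ValueError("NSAF undefined: all spectral counts are zero")
    return {acc: v / total for acc, v in saf.items()}


def top3_xic(observation: ProteinObservation) -> float:
    """Mean of the three largest peptide areas (fewer if fewer exist; 0 if none)."""
    areas = sorted(observation.peptide_areas, reverse=True)[:3]
    if not areas:
        return 0.0
    return float(sum(areas) / len(areas))


def complex_abundance(complex_: ComplexRecord, per_protein: Mapping[str, float]) -> float:
    """Mean abundance over ALL subunits; unidentified subunits count as 0."""
    return sum(per_protein.get(acc, 0.0) for acc in complex_.subunits) / len(
        complex_.subunits
    )


def abundance_table(
    observations: Sequence[ProteinObservation],
    complexes: Sequence[ComplexRecord],
    method: str = "nsaf",
) -> dict[str, float]:
    """Per-complex abundance under one method ("nsaf" or "top3")."""
    if method == "nsaf":
        per_protein = nsaf(observations)
    elif method == "top3":
        per_protein = {o.accession: top3_xic(o) for o in observations}
    else:
        raise ValueError(f"unknown quantification method {method!r}")
    return {c.complex_id: complex_abundance(c, per_protein) for c in complexes}


def quant_correlation(
    tableA: Mapping[str, float], tableB: Mapping[str, float], log: bool = False
) -> float:
    """Pearson r between two per-complex abundance tables.

    Computed on raw abundances by default; ``log=True`` applies log10 with a
    small offset first.  Requires the same complex set, >= 3 complexes, and
    non-zero variance in both tables.
    """
    if set(tableA) != set(tableB):
        raise ValueError("abundance tables cover different complex sets")
    keys = sorted(tableA)
    if len(keys) < 3:
        raise ValueError("need at least 3 complexes for a correlation")
    xs = [tableA[k] for k in keys]
    ys = [tableB[k] for k in keys]
    if log:
        eps = 1e-12
        xs = [math.log10(x + eps) for x in xs]
        ys = [math.log10(y + eps) for y in ys]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("Pearson r undefined: zero variance")
    r, _ = stats.pearsonr(xs, ys)
    return float(r)


def stoichiometry_ratio(
    subunitsA: Iterable[str],
    subunitsB: Iterable[str],
    per_protein: Mapping[str, float],
) -> float:
    """Ratio of mean per-protein abundance over set A to that over set B.

    Used to estimate the relative stoichiometry of two assemblies (e.g. the
    regulatory cap vs. the core barrel of a protease) from MS abundances.
    Missing proteins contribute 0; the B-side mean must be positive.
    """
    sA, sB = list(set(subunitsA)), list(set(subunitsB))
    if not sA or not sB:
        raise ValueError("both subunit sets must be non-empty")
    meanA = sum(per_protein.get(a, 0.0) for a in sA) / len(sA)
    meanB = sum(per_protein.get(b, 0.0) for b in sB) / len(sB)
    if meanB <= 0:
        raise ValueError("denominator subunit set has zero mean abundance")
    return meanA / meanB
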