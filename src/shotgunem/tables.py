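"""TSV readers/writers for the pipeline's tabular interchange formats.

* proteins.tsv — accession, length, spectral_count, peptide_areas
  (semicolon-separated floats)
* complexes.tsv — complex_id, name, subunits (semicolon-separated accessions);
  CORUM-convertible
* truth.tsv — particle ground truth: particle_id/center, label, Euler angles,
  shifts
"""

from __future__ import annotations

import pandas as pd

from .complexome import ComplexRecord
from .quant import ProteinObservation

__all__ = [
    "read_proteins",
    "write_proteins",
    "read_complex_db",
    "write_complex_db",
    "write_particle_truth",
]


def write_proteins(observations, path) -> None:
    pd.DataFrame(
        {
            "accession": [o.accession for o in observations],
            "length": [o.length for o in observations],
            "spectral_count": [o.spectral_count for o in observations],
            "peptide_areas": [
                ";".join(repr(a) for a in o.peptide_areas) for o in observations
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_proteins(path) -> list[ProteinObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    out = []
    for row in df.itertuples(index=False):
        areas = (
            [float(a) for a in str(row.peptide_areas).split(";") if a]
            if isinstance(row.peptide_areas, str) and row.peptide_areas
            else []
        )
        out.append(
            ProteinObservation(row.accession, int(row.length),
                               int(row.spectral_count), areas)
        )
    return out


def write_complex_db(complexes, path) -> None:
    pd.DataFrame(
        {
            "complex_id": [c.complex_id for c in complexes],
            "name": [c.name for c in complexes],
            "subunits": [";".join(sorted(c.subunits)) for c in complexes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_complex_db(path) -> list[ComplexRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ComplexRecord(row.complex_id, row.name,
                      frozenset(s for s in row.subunits.split(";") if s))
        for row in df.itertuples(index=False)
    ]


def write_particle_truth(labels, orientations, path) -> None:
    pd.DataFrame(
        {
            "particle_id": range(len(labels)),
            "label": list(labels),
            "rot": [o.rot for o in orientations],
            "tilt": [o.tilt for o in orientations],
            "psi": [o.psi for o in orientations],
            "dx": [o.shift[0] for o in orientations],
            "dy": [o.shift[1] for o in orientations],
        }
    ).to_csv(path, sep="\t", index=False)
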