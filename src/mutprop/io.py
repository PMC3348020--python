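"""File readers and writers for the pipeline's interchange formats.

Formats (all plain text):

* mutations: CSV with header ``receptor_id,position,wild,mutant,response``
  and optional ``location_class`` (TM | loop | unknown); positions 1-based.
* property table: TSV (see :mod:`mutprop.properties`).
* receptor sequence: FASTA, single record.
* coordinates: PDB, CA atoms of one chain (first model, first altloc); PDB
  residue numbers map to 1-based sequence positions through a user-supplied
  offset (sequence position = PDB number + offset; insertion codes are not
  supported).
* reports: TSV and JSON (written by the result objects themselves).

Sign convention for responses: ``response = value(mutant) - value(wild)``;
the "increase" class is positive.  The package never infers direction from
a label's text -- supply consistently signed values.
"""

from __future__ import annotations

import warnings
from os import PathLike

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .errors import DatasetValidationError, StructureError
from .features import MutantDataset, MutantRecord, StructureContext

MUTATION_COLUMNS = ("receptor_id", "position", "wild", "mutant", "response")


def read_fasta_sequence(path: str | PathLike) -> str:
    """Read a single-record FASTA file and return the sequence string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise DatasetValidationError(
            f"expected exactly one FASTA record in {path}, found {len(records)}"
        )
    return str(records[0].seq).upper()


def write_fasta_sequence(sequence: str, path: str | PathLike, name: str = "receptor") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")


def read_mutation_table(
    path: str | PathLike,
    sequence: str | None = None,
    structure: StructureContext | None = None,
    response_label: str = "response",
) -> MutantDataset:
    """Read a mutant CSV into a validated :class:`MutantDataset`.

    When a sequence is given, every record's wild residue is checked against
    it; mismatches are reported with their row numbers.
    """
    frame = pd.read_csv(path, dtype={"wild": str, "mutant": str},
                        float_precision="round_trip")
    missing = [c for c in MUTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetValidationError(
            f"mutation table {path} lacks column(s): {', '.join(missing)}"
        )
    if frame["response"].isna().any():
        rows = frame.index[frame["response"].isna()].tolist()
        raise DatasetValidationError(f"missing response value at row(s) {rows}")
    if not np.issubdtype(frame["response"].dtype, np.number):
        raise DatasetValidationError("non-numeric response value(s) in mutation table")
    records = []
    for i, row in frame.iterrows():
        loc = str(row["location_class"]) if "location_class" in frame.columns else "unknown"
        try:
            records.append(
                MutantRecord(
                    receptor_id=str(row["receptor_id"]),
                    position=int(row["position"]),
                    wild=str(row["wild"]).strip().upper(),
                    mutant=str(row["mutant"]).strip().upper(),
                    response=float(row["response"]),
                    location_class=loc if loc in ("TM", "loop") else "unknown",
                )
            )
        except DatasetValidationError as exc:
            raise DatasetValidationError(f"row {i}: {exc}") from exc
    return MutantDataset(
        records=records, sequence=sequence, structure=structure,
        response_label=response_label,
    )


def write_mutation_table(dataset: MutantDataset, path: str | PathLike) -> None:
    rows = [
        {
            "receptor_id": r.receptor_id, "position": r.position, "wild": r.wild,
            "mutant": r.mutant, "response": r.response,
            "location_class": r.location_class,
        }
        for r in dataset.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_structure(
    path: str | PathLike,
    chain: str | None = None,
    offset: int = 0,
) -> StructureContext:
    """Read CA coordinates of one chain from a PDB file.

    Uses the first model; for each residue the CA atom (first altloc) is the
    representative point.  ``offset`` maps PDB residue numbers to 1-based
    sequence positions (position = PDB number + offset).  Residues with
    insertion codes or without a CA atom are skipped with a warning;
    non-standard residues are skipped.
    """
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models())
    chains = {c.id: c for c in model.get_chains()}
    if chain is None:
        if len(chains) != 1:
            raise StructureError(
                f"{path} has chains {sorted(chains)}; specify one explicitly"
            )
        chain = next(iter(chains))
    if chain not in chains:
        raise StructureError(f"chain {chain!r} not in {path} (has {sorted(chains)})")
    positions, residues, coords = [], [], []
    for res in chains[chain].get_residues():
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue
        if icode.strip():
            warnings.warn(f"skipping residue {resseq}{icode}: insertion codes unsupported",
                          stacklevel=2)
            continue
        one = protein_letters_3to1.get(res.get_resname().upper())
        if one is None or "CA" not in res:
            continue
        positions.append(resseq + offset)
        residues.append(one)
        coords.append(res["CA"].get_coord())
    if not positions:
        raise StructureError(f"no usable CA atoms in chain {chain!r} of {path}")
    order = np.argsort(positions)
    return StructureContext(
        positions=tuple(int(positions[i]) for i in order),
        residues=tuple(residues[i] for i in order),
        coords=np.asarray(coords, dtype=float)[order],
    )


def write_structure(structure: StructureContext, path: str | PathLike,
                    chain: str = "A") -> None:
    """Write a CA-only trace as fixed-width PDB ATOM records (synthetic structures)."""
    one_to_three = {v: k for k, v in protein_letters_3to1.items()}
    with open(path, "w", encoding="utf-8") as fh:
        for serial, (pos, res, xyz) in enumerate(
            zip(structure.positions, structure.residues, structure.coords), start=1
        ):
            fh.write(
                f"ATOM  {serial:5d}  CA  {one_to_three[res]:>3s} {chain}{pos:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
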