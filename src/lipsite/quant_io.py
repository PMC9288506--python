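"""Input/output: peptide quantification reports, PDB structures, result tables.

The peptide report is a neutral long-format TSV/CSV (one row per peptide x
sample) with a configurable ``column_map`` so exports from different DIA
search tools can be adapted without code changes.  Structures are read and
written as PDB (fixed-width v3.3 records) through biotite; the in-memory
representation is a plain chain -> residue -> atom hierarchy with element
symbols, standard atomic masses and coordinates in Angstrom.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

from .doses import parse_dose_label
from .errors import (
    DuplicateKeyError,
    EmptyTableError,
    InvalidQuantityError,
    MissingColumnError,
    StructureParseError,
    UnknownElementError,
)

# ---------------------------------------------------------------------------
# Peptide quantification table
# ---------------------------------------------------------------------------

#: canonical column names of a PeptideQuantTable (long format)
QUANT_COLUMNS = [
    "protein_id",
    "modified_sequence",
    "stripped_sequence",
    "dose",
    "replicate",
    "quantity",
]

#: default mapping canonical name -> input column name
DEFAULT_COLUMN_MAP = {
    "protein_id": "protein_id",
    "modified_sequence": "modified_sequence",
    "stripped_sequence": "stripped_sequence",  # optional; derived when absent
    "dose": "dose",
    "replicate": "replicate",
    "quantity": "quantity",
}

_MODIFICATION_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)")


def strip_modifications(modified_sequence: str) -> str:
    """Remove bracketed modification annotations, e.g.
    ``"C[Carbamidomethyl]TLADIK" -> "CTLADIK"``."""
    stripped = _MODIFICATION_RE.sub("", modified_sequence)
    return stripped.replace("_", "").strip().upper()


def validate_quant_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the PeptideQuantTable invariants; returns the table unchanged.

    Raises named errors for non-positive quantities and duplicate
    (modified_sequence, dose, replicate) keys.
    """
    if table.empty:
        raise EmptyTableError("peptide quant table has no rows")
    bad = table.index[~(pd.to_numeric(table["quantity"], errors="coerce") > 0)]
    if len(bad):
        raise InvalidQuantityError(list(bad))
    key = ["modified_sequence", "dose", "replicate"]
    dup_mask = table.duplicated(subset=key, keep=False)
    if dup_mask.any():
        dups = table.loc[dup_mask, key].drop_duplicates()
        raise DuplicateKeyError([tuple(r) for r in dups.itertuples(index=False)])
    return table


def read_peptide_report(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a long-format peptide quantification report into a validated
    PeptideQuantTable.

    Parameters
    ----------
    path
        TSV or CSV file with one row per (peptide, sample).
    column_map
        Mapping from canonical column names (:data:`QUANT_COLUMNS`) to the
        input file's column names; unspecified entries use
        :data:`DEFAULT_COLUMN_MAP`.  ``stripped_sequence`` may be omitted
        from the input, in which case it is derived by stripping bracketed
        modification annotations from ``modified_sequence``.
    sep
        Field separator; ``None`` infers TSV for ``.tsv``/``.txt``,
        CSV otherwise.

    Returns
    -------
    pandas.DataFrame
        Columns :data:`QUANT_COLUMNS`; ``dose`` in molar (parsed from labels
        such as ``"2mM"`` when not already numeric), ``quantity`` positive.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep)
    if raw.empty:
        raise EmptyTableError(f"{path} contains no data rows")

    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    out = pd.DataFrame(index=raw.index)
    for canonical in ["protein_id", "modified_sequence", "dose", "replicate", "quantity"]:
        source = cmap[canonical]
        if source not in raw.columns:
            raise MissingColumnError(source, list(raw.columns))
        out[canonical] = raw[source]

    stripped_src = cmap.get("stripped_sequence")
    if stripped_src and stripped_src in raw.columns:
        out["stripped_sequence"] = raw[stripped_src].astype(str).str.upper()
    else:
        out["stripped_sequence"] = out["modified_sequence"].astype(str).map(
            strip_modifications
        )

    out["dose"] = out["dose"].map(parse_dose_label)
    out["quantity"] = pd.to_numeric(out["quantity"], errors="coerce")
    out = out[QUANT_COLUMNS]
    validate_quant_table(out)
    return out.reset_index(drop=True)


def write_peptide_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write a PeptideQuantTable in the package's neutral TSV dialect."""
    table[QUANT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Structure model
# ---------------------------------------------------------------------------

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k not in {"MSE"}}


@dataclass(frozen=True)
class Atom:
    """One atom: PDB atom name, element symbol, unified atomic mass, Angstrom
    coordinates."""

    name: str
    element: str
    mass: float
    x: float
    y: float
    z: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class Residue:
    """One residue with author numbering (PDB resSeq + insertion code)."""

    name: str                      # 3-letter code
    number: int                    # author residue number
    insertion_code: str = ""
    atoms: tuple[Atom, ...] = ()
    hetero: bool = False

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class StructureModel:
    """Chains -> ordered residues -> atoms, as parsed from a PDB file."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of the resolved residues of a chain, ordered
        by (author number, insertion code); unknown residues become 'X'."""
        return "".join(
            r.one_letter for r in self.chains[chain_id] if not r.hetero
        )

    def atoms_of(self, chain_id: str) -> list[Atom]:
        return [a for r in self.chains[chain_id] for a in r.atoms]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for rs in self.chains.values() for r in rs)


def _element_mass(element: str, atom_desc: str) -> float:
    mass = struc_info.mass(element.capitalize())
    if mass is None:
        raise UnknownElementError(atom_desc)
    return float(mass)


_NAME_ELEMENT_RE = re.compile(r"([A-Z]{1,2})")


def _element_from_name(atom_name: str) -> str:
    """Heuristic element from a PDB atom name when columns 77-78 are blank:
    strip digits/primes, take the leading letters; two-letter names that are
    standard protein heavy-atom prefixes collapse to their first letter."""
    cleaned = re.sub(r"[^A-Za-z]", "", atom_name).upper()
    if not cleaned:
        return ""
    if cleaned[0] in {"C", "N", "O", "S", "P", "H"}:
        return cleaned[0]
    return cleaned[:2]


def read_structure(
    path: str | Path,
    altloc_policy: str = "first",
    model_index: int = 1,
    include_hetatm: bool = False,
    include_hydrogens: bool = False,
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Elements are taken from the record's element columns when present, with a
    fallback heuristic from the atom name.  Alternate locations are resolved
    per ``altloc_policy`` (``"first"`` keeps blank or 'A'); only the requested
    MODEL is retained; hydrogens are excluded by default (crystal structures
    rarely resolve them and they would bias the center of mass).
    """
    pdb = PDBFile.read(str(path))
    try:
        array = pdb.get_structure(
            model=model_index, altloc="first" if altloc_policy == "first" else "all"
        )
    except Exception as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if array.array_length() == 0:
        raise StructureParseError(f"{path}: no ATOM records")

    mask = np.ones(array.array_length(), dtype=bool)
    if not include_hetatm:
        mask &= ~array.hetero
    if not mask.any():
        raise StructureParseError(f"{path}: no ATOM records after filtering")
    array = array[mask]

    model = StructureModel()
    order = np.arange(array.array_length())
    chains: dict[str, dict[tuple, dict]] = {}
    for i in order:
        element = str(array.element[i]).strip().upper()
        name = str(array.atom_name[i]).strip()
        if not element:
            element = _element_from_name(name)
        if not element:
            raise UnknownElementError(
                f"chain {array.chain_id[i]} residue {array.res_id[i]} atom {name!r}"
            )
        if not include_hydrogens and element in {"H", "D"}:
            continue
        desc = f"chain {array.chain_id[i]} residue {array.res_id[i]} atom {name!r}"
        mass = _element_mass(element, desc)
        chain_id = str(array.chain_id[i])
        icode = str(array.ins_code[i]).strip() if hasattr(array, "ins_code") else ""
        key = (int(array.res_id[i]), icode)
        res_entry = chains.setdefault(chain_id, {}).setdefault(
            key,
            {
                "name": str(array.res_name[i]).strip(),
                "hetero": bool(array.hetero[i]),
                "atoms": [],
            },
        )
        x, y, z = (float(v) for v in array.coord[i])
        res_entry["atoms"].append(Atom(name, element, mass, x, y, z))

    for chain_id, residues in chains.items():
        ordered = []
        for (number, icode) in sorted(residues, key=lambda k: (k[0], k[1])):
            entry = residues[(number, icode)]
            ordered.append(
                Residue(
                    name=entry["name"],
                    number=number,
                    insertion_code=icode,
                    atoms=tuple(entry["atoms"]),
                    hetero=entry["hetero"],
                )
            )
        model.chains[chain_id] = ordered
    if not model.chains:
        raise StructureParseError(f"{path}: no ATOM records")
    return model


def structure_to_atom_array(model: StructureModel) -> struc.AtomArray:
    """Convert a :class:`StructureModel` back to a biotite AtomArray."""
    n = model.n_atoms()
    array = struc.AtomArray(n)
    i = 0
    for chain_id, residues in model.chains.items():
        for res in residues:
            for atom in res.atoms:
                array.chain_id[i] = chain_id
                array.res_id[i] = res.number
                array.ins_code[i] = res.insertion_code
                array.res_name[i] = res.name
                array.atom_name[i] = atom.name
                array.element[i] = atom.element
                array.hetero[i] = res.hetero
                array.coord[i] = (atom.x, atom.y, atom.z)
                i += 1
    return array


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` as a PDB file (fixed-width records)."""
    pdb = PDBFile()
    pdb.set_structure(structure_to_atom_array(model))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Binding-site outputs
# ---------------------------------------------------------------------------


def write_site_outputs(prediction, prefix: str | Path, structure: StructureModel | None = None):
    """Write the binding-site prediction: a TSV of contributing peptides and
    a PDB with the analysed chain plus one HETATM pseudo-atom at the center
    of mass (residue ``SIT``, atom ``COM``) for molecular-graphics viewing.

    Returns the two paths written (tsv, pdb).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = prefix.with_name(prefix.name + "_site.tsv")
    pdb_path = prefix.with_name(prefix.name + "_site.pdb")

    com = prediction.com
    rows = []
    for m in prediction.contributing_peptides:
        rows.append(
            {
                "peptide": m.peptide,
                "chain": m.chain_id,
                "start_residue": m.start,
                "end_residue": m.end,
                "n_residues": m.matched_residues,
                "n_atoms": len(m.atoms),
                "r_squared": getattr(m, "r_squared", float("nan")),
                "ec50_molar": getattr(m, "ec50", float("nan")),
                "com_x": com[0],
                "com_y": com[1],
                "com_z": com[2],
                "nearby_residues": ";".join(
                    f"{name}{num}" for name, num, _ in prediction.nearby_residues
                ),
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)

    out_model = StructureModel()
    if structure is not None:
        chain_id = prediction.contributing_peptides[0].chain_id
        out_model.chains[chain_id] = list(structure.chains[chain_id])
    pseudo = Residue(
        name="SIT",
        number=9999,
        atoms=(Atom("COM", "C", _element_mass("C", "pseudo-atom"), *com),),
        hetero=True,
    )
    target_chain = "Z" if "Z" not in out_model.chains else "Y"
    out_model.chains[target_chain] = [pseudo]
    write_structure(out_model, pdb_path)
    return tsv_path, pdb_path
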