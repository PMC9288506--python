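"""Peptide-to-structure mapping and center-of-mass site triangulation.

The binding-site prediction takes the top dose-responsive peptides, locates
each as an exact substring of one chain's resolved one-letter sequence, pools
the atoms of the matched residues (union; atoms shared by overlapping
peptides counted once) and reports the mass-weighted center of mass of that
pool, together with the residues in its neighbourhood.  Peptides from a
well-behaved dose-response experiment cluster around the ligand site, so
their pooled center of mass triangulates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AmbiguousMappingError
from .quant_io import Atom, Residue, StructureModel


@dataclass(frozen=True)
class PeptideMapping:
    """A peptide located on a structure chain.

    ``start``/``end`` are author residue numbers (inclusive);
    ``unresolved_residues`` counts author-numbering gaps inside the matched
    range (residues present in the construct but missing from the model).
    A mapping with no atoms at all is unusable.
    """

    peptide: str
    chain_id: str
    start: int
    end: int
    matched_residues: int
    atoms: tuple[Atom, ...]
    residues: tuple[Residue, ...] = ()
    unresolved_residues: int = 0
    mapped: bool = True
    r_squared: float = float("nan")
    ec50: float = float("nan")

    @property
    def usable(self) -> bool:
        return self.mapped and len(self.atoms) > 0


def unmapped(peptide: str, chain_id: str) -> PeptideMapping:
    """Named non-fatal marker for a peptide absent from the chain."""
    return PeptideMapping(
        peptide=peptide, chain_id=chain_id, start=-1, end=-1,
        matched_residues=0, atoms=(), mapped=False,
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    positions, i = [], haystack.find(needle)
    while i != -1:
        positions.append(i)
        i = haystack.find(needle, i + 1)
    return positions


def map_peptide_to_structure(
    stripped_sequence: str,
    structure: StructureModel,
    chain_id: str,
    il_equivalent: bool = False,
) -> PeptideMapping:
    """Locate a peptide as an exact substring of a chain's resolved sequence.

    Isoleucine and leucine are distinct by default (structures resolve them
    even though MS cannot); ``il_equivalent=True`` folds I onto L on both
    sides before matching.  No match returns an :func:`unmapped` marker;
    multiple matches raise :class:`~lipsite.errors.AmbiguousMappingError`
    listing every position so the caller can disambiguate.
    """
    if chain_id not in structure.chains:
        raise KeyError(f"chain {chain_id!r} not in structure: {structure.chain_ids}")
    residues = [r for r in structure.chains[chain_id] if not r.hetero]
    sequence = "".join(r.one_letter for r in residues)
    query = stripped_sequence.upper()
    hay, needle = sequence, query
    if il_equivalent:
        hay = hay.replace("I", "L")
        needle = needle.replace("I", "L")
    positions = _find_all(hay, needle)
    if not positions:
        return unmapped(stripped_sequence, chain_id)
    if len(positions) > 1:
        raise AmbiguousMappingError(stripped_sequence, positions)
    start_idx = positions[0]
    matched = residues[start_idx : start_idx + len(query)]
    atoms = tuple(a for r in matched for a in r.atoms)
    start_num, end_num = matched[0].number, matched[-1].number
    span = end_num - start_num + 1
    unresolved = max(0, span - len(matched))
    return PeptideMapping(
        peptide=stripped_sequence,
        chain_id=chain_id,
        start=start_num,
        end=end_num,
        matched_residues=len(matched),
        atoms=atoms,
        residues=tuple(matched),
        unresolved_residues=unresolved,
    )


def center_of_mass(atoms, weighting: str = "mass") -> np.ndarray:
    """Weighted mean coordinate of an atom set: sum(w_i x_i) / sum(w_i).

    ``weighting="mass"`` uses standard atomic masses by element;
    ``"geometric"`` is the unweighted mean.
    """
    atoms = list(atoms)
    if not atoms:
        raise ValueError("center_of_mass requires at least one atom")
    if weighting not in {"mass", "geometric"}:
        raise ValueError(f"weighting must be 'mass' or 'geometric', got {weighting!r}")
    coords = np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)
    if weighting == "mass":
        w = np.array([a.mass for a in atoms], dtype=float)
    else:
        w = np.ones(len(atoms))
    return (w[:, None] * coords).sum(axis=0) / w.sum()


@dataclass(frozen=True)
class BindingSitePrediction:
    """Triangulated site: pooled-atom center of mass plus context."""

    com: np.ndarray
    contributing_peptides: tuple[PeptideMapping, ...]
    atom_count: int
    weighting: str
    neighbor_radius: float
    #: (residue name, author number, distance to CoM), sorted by distance
    nearby_residues: tuple[tuple[str, int, float], ...] = ()


def predict_binding_site(
    top_peptides,
    structure: StructureModel,
    weighting: str = "mass",
    neighbor_radius: float = 10.0,
    deduplicate: bool = True,
) -> BindingSitePrediction:
    """Pool the atoms of the mapped top peptides and triangulate the site.

    Atoms shared by overlapping peptides are counted once by default
    (``deduplicate=False`` keeps the multiset).  ``nearby_residues`` lists
    every residue of the analysed chain with any atom within
    ``neighbor_radius`` Angstrom of the center of mass, nearest first.
    """
    mappings = [m for m in top_peptides if m.usable]
    if not mappings:
        raise ValueError("no usable peptide mappings: nothing to triangulate")

    if deduplicate:
        seen, atoms = set(), []
        for m in mappings:
            for res, in_res_atoms in _atoms_by_residue(m):
                for a in in_res_atoms:
                    key = (m.chain_id, res.number, res.insertion_code, a.name)
                    if key not in seen:
                        seen.add(key)
                        atoms.append(a)
    else:
        atoms = [a for m in mappings for a in m.atoms]

    com = center_of_mass(atoms, weighting=weighting)

    chain_id = mappings[0].chain_id
    nearby = []
    for res in structure.chains[chain_id]:
        if not res.atoms:
            continue
        coords = np.array([[a.x, a.y, a.z] for a in res.atoms])
        d = float(np.sqrt(((coords - com) ** 2).sum(axis=1)).min())
        if d <= neighbor_radius:
            nearby.append((res.name, res.number, d))
    nearby.sort(key=lambda t: t[2])

    return BindingSitePrediction(
        com=com,
        contributing_peptides=tuple(mappings),
        atom_count=len(atoms),
        weighting=weighting,
        neighbor_radius=neighbor_radius,
        nearby_residues=tuple(nearby),
    )


def _atoms_by_residue(mapping: PeptideMapping):
    if mapping.residues:
        for res in mapping.residues:
            yield res, res.atoms
    else:  # fall back to a synthetic residue grouping
        yield Residue(name="UNK", number=mapping.start), mapping.atoms


def selection_string(mappings) -> str:
    """Plain-text residue-range selection of the mapped peptides, in the
    ``chain/start-end`` style molecular-graphics tools accept."""
    parts = [f"{m.chain_id}/{m.start}-{m.end}" for m in mappings if m.usable]
    return " ".join(parts)


@dataclass(frozen=True)
class OverlapReport:
    """Residue-range overlaps between two peptide sets."""

    pairs: tuple[tuple[str, str], ...]
    n_overlapping_pairs: int
    peptides_a_overlapping: tuple[str, ...]
    peptides_b_overlapping: tuple[str, ...]


def compare_peptide_sets(set_a, set_b) -> OverlapReport:
    """Report peptides from two mapped sets whose inclusive residue ranges
    share at least one residue (e.g. sites found with two different
    compounds)."""
    pairs = []
    for a in set_a:
        for b in set_b:
            if not (a.usable and b.usable):
                continue
            if a.chain_id == b.chain_id and a.start <= b.end and b.start <= a.end:
                pairs.append((a.peptide, b.peptide))
    return OverlapReport(
        pairs=tuple(pairs),
        n_overlapping_pairs=len(pairs),
        peptides_a_overlapping=tuple(sorted({p for p, _ in pairs})),
        peptides_b_overlapping=tuple(sorted({q for _, q in pairs})),
    )
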