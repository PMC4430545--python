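"""Synthetic structure fixtures: polyalanine-like backbones built from
ideal dihedrals, pseudo-solvent placement at controlled hydrogen-bonding
geometry, and PDB/TSV round-trips.

The backbone model carries five atoms per residue (N, H, CA, C, O) —
enough for amide-donor/carbonyl-acceptor hydrogen-bond analysis without
side chains or terminal caps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, GeometryError, LabelingError

__all__ = [
    "StructureFrame",
    "generate_helix_fixture",
    "generate_solvated_fixture",
    "write_frame",
    "read_frame",
    "ALPHA_HELIX_PHI",
    "ALPHA_HELIX_PSI",
]

ALPHA_HELIX_PHI = -57.0
ALPHA_HELIX_PSI = -47.0

# Ideal backbone geometry (lengths in A, angles in degrees)
_B = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "N-H": 1.010,
    "CA-C-N": 116.2, "C-N-CA": 121.7, "N-CA-C": 111.2,
    "CA-C-O": 120.8, "CA-N-H": 118.2, "OMEGA": 180.0,
}

_WATER_OH = 0.9572
_WATER_HOH = 104.52  # degrees


@dataclass
class StructureFrame:
    """Labelled atom coordinates for hydrogen-bond analysis.

    Roles are carried as boolean donor/acceptor flags on heavy atoms plus
    a per-atom donor link for polar hydrogens (``h_donor[i]`` is the
    index of the donor heavy atom if atom i is a polar hydrogen, else
    -1).  ``end_pair`` tags the two peptide atoms defining the pulled
    end-to-end distance.
    """

    coords: np.ndarray
    names: list
    elements: list
    resids: np.ndarray
    is_solvent: np.ndarray
    is_donor: np.ndarray
    is_acceptor: np.ndarray
    h_donor: np.ndarray
    end_pair: tuple = (0, 0)
    #: alternate end-to-end tag choices, keyed by atom-name convention
    end_tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        self.resids = np.asarray(self.resids, dtype=int)
        self.is_solvent = np.asarray(self.is_solvent, dtype=bool)
        self.is_donor = np.asarray(self.is_donor, dtype=bool)
        self.is_acceptor = np.asarray(self.is_acceptor, dtype=bool)
        self.h_donor = np.asarray(self.h_donor, dtype=int)
        for name in ("resids", "is_solvent", "is_donor", "is_acceptor", "h_donor"):
            if len(getattr(self, name)) != n:
                raise ConfigurationError(f"StructureFrame field {name} length mismatch")
        if len(self.names) != n or len(self.elements) != n:
            raise ConfigurationError("StructureFrame names/elements length mismatch")
        if np.any(self.resids < 1):
            raise ConfigurationError("residue indices must be >= 1")
        for h in np.flatnonzero(self.h_donor >= 0):
            d = self.h_donor[h]
            if not (0 <= d < n) or not self.is_donor[d]:
                raise LabelingError(f"hydrogen {h} links to atom {d} which is not a donor")
        i, j = self.end_pair
        if i != j:
            if self.is_solvent[i] or self.is_solvent[j]:
                raise ConfigurationError("end-to-end tagged atoms must be peptide atoms")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def peptide_mask(self) -> np.ndarray:
        return ~self.is_solvent

    def end_to_end(self, tags: str | None = None) -> float:
        """Distance between the tagged end atoms; ``tags`` selects an
        alternate registered tag pair (e.g. 'N' vs 'CA')."""
        i, j = self.end_tags[tags] if tags else self.end_pair
        return float(np.linalg.norm(self.coords[j] - self.coords[i]))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureFrame":
        return replace(self, coords=self.coords @ np.asarray(rotation).T + translation)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, chi: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = r, angle(b,c,d) = theta and
    torsion(a,b,c,d) = chi (both in degrees)."""
    th, ch = np.radians(theta), np.radians(chi)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * np.cos(th), r * np.sin(th) * np.cos(ch), r * np.sin(th) * np.sin(ch)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def generate_helix_fixture(n_res: int, phi: float = ALPHA_HELIX_PHI, psi: float = ALPHA_HELIX_PSI) -> StructureFrame:
    """Ideal backbone-only polyalanine-like chain from repeated (phi, psi).

    Five atoms per residue in order N, H, CA, C, O; amide N-H labelled as
    donors, carbonyl O as acceptors.  End-to-end tag pairs are registered
    for both the terminal nitrogens (default) and the terminal CA atoms.
    """
    if n_res < 2:
        raise ConfigurationError("generate_helix_fixture requires n_res >= 2")
    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))
    # seed the first residue in the xy-plane
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [_B["N-CA"], 0.0, 0.0]
    ang = np.radians(_B["N-CA-C"])
    C[0] = CA[0] + _B["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], _B["C-N"], _B["CA-C-N"], psi)
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], _B["N-CA"], _B["C-N-CA"], _B["OMEGA"])
        C[i] = _place(C[i - 1], N[i], CA[i], _B["CA-C"], _B["N-CA-C"], phi)
    O = np.empty((n_res, 3))
    H = np.empty((n_res, 3))
    for i in range(n_res):
        if i < n_res - 1:
            O[i] = _place(N[i], CA[i], C[i], _B["C-O"], _B["CA-C-O"], psi + 180.0)
        else:  # no following N; same placement rule keeps the chain ideal
            O[i] = _place(N[i], CA[i], C[i], _B["C-O"], _B["CA-C-O"], psi + 180.0)
        ref = C[i - 1] if i > 0 else C[i]
        H[i] = _place(ref, CA[i], N[i], _B["N-H"], _B["CA-N-H"], 180.0)

    coords, names, elements, resids = [], [], [], []
    is_donor, is_acceptor, h_donor = [], [], []
    for i in range(n_res):
        base = len(names)
        for name, xyz in (("N", N[i]), ("H", H[i]), ("CA", CA[i]), ("C", C[i]), ("O", O[i])):
            coords.append(xyz)
            names.append(name)
            elements.append(name[0])
            resids.append(i + 1)
            is_donor.append(name == "N")
            is_acceptor.append(name == "O")
            h_donor.append(base if name == "H" else -1)
    n_at = len(names)
    frame = StructureFrame(
        coords=np.array(coords),
        names=names,
        elements=elements,
        resids=np.array(resids),
        is_solvent=np.zeros(n_at, dtype=bool),
        is_donor=np.array(is_donor),
        is_acceptor=np.array(is_acceptor),
        h_donor=np.array(h_donor),
        end_pair=(0, 5 * (n_res - 1)),  # terminal nitrogens
    )
    frame.end_tags = {"N": (0, 5 * (n_res - 1)), "CA": (2, 5 * (n_res - 1) + 2)}
    return frame


def _water(o: np.ndarray, u1: np.ndarray, resid: int, base: int):
    """Three-site pseudo-water with O at ``o`` and the first O-H bond along
    unit vector ``u1``; returns (coords, labelling columns)."""
    u1 = u1 / np.linalg.norm(u1)
    # second hydrogen in the plane spanned by u1 and an arbitrary normal
    ref = np.array([0.0, 0.0, 1.0]) if abs(u1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    perp = np.cross(u1, ref)
    perp /= np.linalg.norm(perp)
    th = np.radians(_WATER_HOH)
    u2 = np.cos(th) * u1 + np.sin(th) * perp
    h1 = o + _WATER_OH * u1
    h2 = o + _WATER_OH * u2
    coords = [o, h1, h2]
    names = ["OW", "HW1", "HW2"]
    elements = ["O", "H", "H"]
    resids = [resid] * 3
    is_donor = [True, False, False]
    is_acceptor = [True, False, False]
    h_donor = [-1, base, base]
    return coords, names, elements, resids, is_donor, is_acceptor, h_donor


def generate_solvated_fixture(
    frame: StructureFrame,
    n_waters: int,
    hb_placed: int,
    seed: int,
    min_far_distance: float = 6.0,
) -> StructureFrame:
    """Append three-site pseudo-waters to a peptide frame.

    Exactly ``hb_placed`` waters are placed at ideal hydrogen-bonding
    geometry against distinct free peptide donors/acceptors; the rest sit
    on a jittered lattice at least ``min_far_distance`` from every
    peptide atom and too far apart to bond each other.  Deterministic for
    a given seed; the construction is verified by detection and a
    :class:`GeometryError` is raised if the achieved counts differ.
    """
    from .hbond import HBClass, classify_counts, detect_hbonds

    if hb_placed > n_waters:
        raise ConfigurationError("hb_placed must be <= n_waters")
    rng = np.random.default_rng(seed)
    pep = frame
    intra_before = classify_counts(detect_hbonds(pep), pep)

    # free donors: amide N whose hydrogen is in no intrapeptide bond;
    # free acceptors: carbonyl O accepting no intrapeptide bond
    bonds = detect_hbonds(pep)
    bonded_h = {b.hydrogen for b in bonds}
    bonded_a = {b.acceptor for b in bonds}
    donor_sites = []
    for h in np.flatnonzero(pep.h_donor >= 0):
        if h not in bonded_h and not pep.is_solvent[h]:
            donor_sites.append(("donor", int(pep.h_donor[h]), int(h)))
    acceptor_sites = []
    for a in np.flatnonzero(pep.is_acceptor & pep.peptide_mask):
        if a not in bonded_a:
            acceptor_sites.append(("acceptor", int(a), -1))
    sites = donor_sites + acceptor_sites
    if len(sites) < hb_placed:
        raise GeometryError(
            f"only {len(sites)} solvent-accessible peptide sites available, "
            f"need {hb_placed}"
        )
    order = rng.permutation(len(sites))

    centroid = pep.coords[pep.peptide_mask].mean(axis=0)
    coords = [pep.coords]
    names = list(pep.names)
    elements = list(pep.elements)
    resids = list(pep.resids)
    is_solvent = list(pep.is_solvent)
    is_donor = list(pep.is_donor)
    is_acceptor = list(pep.is_acceptor)
    h_donor = list(pep.h_donor)
    next_resid = int(pep.resids.max()) + 1
    placed_os: list[np.ndarray] = []

    def append_water(o: np.ndarray, u1: np.ndarray) -> None:
        nonlocal next_resid
        base = len(names)
        c, nm, el, rs, dn, ac, hd = _water(o, u1, next_resid, base)
        coords.append(np.array(c))
        names.extend(nm)
        elements.extend(el)
        resids.extend(rs)
        is_solvent.extend([True] * 3)
        is_donor.extend(dn)
        is_acceptor.extend(ac)
        h_donor.extend(hd)
        next_resid += 1
        placed_os.append(o)

    def candidate(kind: str, heavy: int, hyd: int) -> tuple[np.ndarray, np.ndarray]:
        if kind == "donor":
            # water oxygen accepts: along the N->H direction, 2.9 A from N
            n_xyz, h_xyz = pep.coords[heavy], pep.coords[hyd]
            u = h_xyz - n_xyz
            u /= np.linalg.norm(u)
            return n_xyz + 2.9 * u, u  # O-H bonds point away from the peptide
        # water donates to the carbonyl O: O_w on the C=O axis, H toward O_p
        a_xyz = pep.coords[heavy]
        v = a_xyz - pep.coords[heavy - 1]  # carbonyl C precedes O in the ordering
        v /= np.linalg.norm(v)
        return a_xyz + 2.9 * v, -v

    def bonds_with_peptide(o: np.ndarray, u1: np.ndarray) -> int:
        """Peptide-solvent bonds a tentative water would introduce."""
        base = pep.n_atoms
        c, nm, el, rs, dn, ac, hd = _water(o, u1, int(pep.resids.max()) + 1, base)
        trial = StructureFrame(
            coords=np.vstack([pep.coords, np.array(c)]),
            names=list(pep.names) + nm,
            elements=list(pep.elements) + el,
            resids=np.concatenate([pep.resids, rs]),
            is_solvent=np.concatenate([pep.is_solvent, [True] * 3]),
            is_donor=np.concatenate([pep.is_donor, dn]),
            is_acceptor=np.concatenate([pep.is_acceptor, ac]),
            h_donor=np.concatenate([pep.h_donor, hd]),
            end_pair=pep.end_pair,
        )
        return classify_counts(detect_hbonds(trial), trial)[HBClass.PEPTIDE_SOLVENT]

    used = 0
    for idx in order:
        if used == hb_placed:
            break
        o, u1 = candidate(*sites[idx])
        # accept only sites whose water bonds the peptide exactly once and
        # stays clear of previously placed waters
        if bonds_with_peptide(o, u1) != 1:
            continue
        if placed_os and min(np.linalg.norm(p - o) for p in placed_os) < 5.0:
            continue
        append_water(o, u1)
        used += 1
    if used < hb_placed:
        raise GeometryError(
            f"could only place {used} of {hb_placed} hydrogen-bonded waters at "
            f"clean single-bond geometry"
        )

    # far waters on a jittered lattice well clear of the peptide
    n_far = n_waters - hb_placed
    if n_far > 0:
        span = pep.coords.max(axis=0) - pep.coords.min(axis=0)
        origin = pep.coords.max(axis=0) + np.array([min_far_distance + 4.0, 0.0, 0.0])
        spacing = 6.5
        side = int(np.ceil(n_far ** (1.0 / 3.0)))
        count = 0
        for ix in range(side + 2):
            for iy in range(side + 2):
                for iz in range(side + 2):
                    if count == n_far:
                        break
                    o = origin + spacing * np.array([ix, iy, iz]) + rng.uniform(-0.3, 0.3, 3)
                    d_pep = np.linalg.norm(pep.coords - o, axis=1).min()
                    if d_pep < min_far_distance:
                        continue
                    if placed_os and min(np.linalg.norm(p - o) for p in placed_os) < 5.0:
                        continue
                    u = o - centroid
                    append_water(o, u / np.linalg.norm(u))
                    count += 1
        if count < n_far:
            raise GeometryError("could not place all far waters (lattice exhausted)")

    out = StructureFrame(
        coords=np.vstack(coords),
        names=names,
        elements=elements,
        resids=np.array(resids),
        is_solvent=np.array(is_solvent),
        is_donor=np.array(is_donor),
        is_acceptor=np.array(is_acceptor),
        h_donor=np.array(h_donor),
        end_pair=pep.end_pair,
        end_tags=dict(pep.end_tags),
    )
    counts = classify_counts(detect_hbonds(out), out)
    if counts[HBClass.PEPTIDE_SOLVENT] != hb_placed:
        raise GeometryError(
            f"solvation construction produced {counts[HBClass.PEPTIDE_SOLVENT]} "
            f"peptide-solvent bonds, expected {hb_placed}"
        )
    intra_after = {k: v for k, v in counts.items()
                   if k not in (HBClass.PEPTIDE_SOLVENT, HBClass.SOLVENT_SOLVENT)}
    intra_expect = {k: v for k, v in intra_before.items()
                    if k not in (HBClass.PEPTIDE_SOLVENT, HBClass.SOLVENT_SOLVENT)}
    if intra_after != intra_expect or counts[HBClass.SOLVENT_SOLVENT] != 0:
        raise GeometryError("solvation construction perturbed the bond inventory")
    return out


_ROLE_NAMES = {-1: "other"}


def _role_of(frame: StructureFrame, i: int) -> str:
    if frame.h_donor[i] >= 0:
        return "hydrogen"
    if frame.is_donor[i] and frame.is_acceptor[i]:
        return "donor_acceptor"
    if frame.is_donor[i]:
        return "donor"
    if frame.is_acceptor[i]:
        return "acceptor"
    return "other"


def write_frame(frame: StructureFrame, pdb_path: str | Path, labels_path: str | Path | None = None) -> None:
    """Write a frame as standard PDB plus a sidecar TSV label table.

    The occupancy column encodes the peptide (1.00) / solvent (0.00)
    flag; the TSV is authoritative for roles, donor links and end tags.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = frame.n_atoms
    atoms = struc.AtomArray(n)
    atoms.coord = frame.coords
    atoms.chain_id = np.where(frame.is_solvent, "W", "A")
    atoms.res_id = frame.resids
    atoms.res_name = np.where(frame.is_solvent, "HOH", "ALA")
    atoms.atom_name = np.array(frame.names)
    atoms.element = np.array([e.upper() for e in frame.elements])
    atoms.hetero = frame.is_solvent.copy()
    atoms.set_annotation("occupancy", np.where(frame.is_solvent, 0.0, 1.0))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(pdb_path))

    if labels_path is None:
        labels_path = Path(str(pdb_path)).with_suffix(".labels.tsv")
    with open(labels_path, "w") as fh:
        fh.write("atom_id\trole\tresidue\tsegment\th_donor\tend_tag\n")
        tag_of = {}
        for tag, (i, j) in frame.end_tags.items():
            tag_of.setdefault(i, []).append(f"{tag}:start")
            tag_of.setdefault(j, []).append(f"{tag}:end")
        for i in range(n):
            seg = "solvent" if frame.is_solvent[i] else "peptide"
            tags = ",".join(tag_of.get(i, [])) or "-"
            fh.write(
                f"{i}\t{_role_of(frame, i)}\t{frame.resids[i]}\t{seg}\t{frame.h_donor[i]}\t{tags}\n"
            )


def read_frame(pdb_path: str | Path, labels_path: str | Path | None = None) -> StructureFrame:
    """Reconstruct a frame from PDB + sidecar labels.

    Without a label table, roles fall back to atom-name heuristics
    (N/OW donors, O/OW acceptors, H* linked to the preceding heavy atom)
    and the solvent flag comes from the occupancy column.
    """
    import biotite.structure as struc  # noqa: F401
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(pdb_path))
    atoms = pdb.get_structure(model=1, extra_fields=["occupancy"])
    n = atoms.array_length()
    coords = atoms.coord
    names = list(atoms.atom_name)
    elements = [str(e).capitalize() for e in atoms.element]
    resids = atoms.res_id.astype(int)
    is_solvent = atoms.occupancy < 0.5

    if labels_path is None:
        cand = Path(str(pdb_path)).with_suffix(".labels.tsv")
        labels_path = cand if cand.exists() else None

    is_donor = np.zeros(n, dtype=bool)
    is_acceptor = np.zeros(n, dtype=bool)
    h_donor = np.full(n, -1)
    end_tags: dict = {}
    end_pair = (0, 0)
    if labels_path is not None:
        with open(labels_path) as fh:
            fh.readline()  # header
            for line in fh:
                sid, role, resid, seg, hd, tags = line.rstrip("\n").split("\t")
                i = int(sid)
                resids[i] = int(resid)
                is_solvent[i] = seg == "solvent"
                is_donor[i] = role in ("donor", "donor_acceptor")
                is_acceptor[i] = role in ("acceptor", "donor_acceptor")
                h_donor[i] = int(hd)
                if tags != "-":
                    for t in tags.split(","):
                        tag, which = t.split(":")
                        pair = list(end_tags.get(tag, (0, 0)))
                        pair[0 if which == "start" else 1] = i
                        end_tags[tag] = tuple(pair)
        if "N" in end_tags:
            end_pair = end_tags["N"]
        elif end_tags:
            end_pair = next(iter(end_tags.values()))
    else:
        last_heavy = -1
        for i in range(n):
            el = elements[i]
            if el == "H":
                h_donor[i] = last_heavy
            else:
                last_heavy = i
                if names[i] in ("N", "OW"):
                    is_donor[i] = True
                if names[i] in ("O", "OW", "OXT"):
                    is_acceptor[i] = True
        pep = np.flatnonzero(~is_solvent)
        if pep.size:
            end_pair = (int(pep[0]), int(pep[-1]))

    return StructureFrame(
        coords=coords,
        names=names,
        elements=elements,
        resids=resids,
        is_solvent=is_solvent,
        is_donor=is_donor,
        is_acceptor=is_acceptor,
        h_donor=h_donor,
        end_pair=end_pair,
        end_tags=end_tags,
    )
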