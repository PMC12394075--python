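"""Structural observables for receptor coordinate frames.

Reads single- and multi-model PDB/mmCIF files (via gemmi) into a light
array-of-atoms container and computes the dimer geometry readouts used to
characterize conformational states: reporter-site Cα–Cα distances, the
clamshell (upper–lower lobe) distance, lower-lobe center-of-mass separation,
hydrogen-bond presence, windowed RMSF after rigid superposition and the
inter-subunit helix rotation angle.  All observables are invariant to global
rigid motion of a frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StructureFrame", "ResiduePairSpec", "read_structure_frames", "write_pdb",
    "pair_distance", "clamshell_distance", "lobe_separation", "hbond_present",
    "any_hbond", "window_rmsf", "interhelix_angle", "metrics_table",
]

_FALLBACK_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                  "S": 32.06, "P": 30.974}


def _element_mass(symbol: str) -> float:
    try:
        import gemmi
        w = gemmi.Element(symbol).weight
        if w > 0:
            return float(w)
    except Exception:
        pass
    return _FALLBACK_MASS.get(symbol.strip().upper(), 12.011)


@dataclass
class StructureFrame:
    """One coordinate frame as parallel atom-record arrays (Å)."""

    chains: np.ndarray
    resnums: np.ndarray
    resnames: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    model_index: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def select(self, chain=None, resnums=None, atom_name=None) -> np.ndarray:
        """Indices of atoms matching the given selectors."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chains == chain
        if resnums is not None:
            if np.isscalar(resnums):
                mask &= self.resnums == resnums
            else:
                mask &= np.isin(self.resnums, np.asarray(list(resnums)))
        if atom_name is not None:
            mask &= self.atom_names == atom_name
        return np.flatnonzero(mask)

    def atom(self, chain: str, resnum: int, atom_name: str = "CA") -> np.ndarray:
        """Coordinates of exactly one atom; raises a lookup error otherwise."""
        idx = self.select(chain=chain, resnums=resnum, atom_name=atom_name)
        if idx.size != 1:
            raise KeyError(
                f"selector chain={chain!r} residue {resnum} atom {atom_name!r}"
                f" matched {idx.size} atoms (need exactly 1)")
        return self.coords[int(idx[0])]

    def masses(self) -> np.ndarray:
        uniq = {e: _element_mass(e) for e in np.unique(self.elements)}
        return np.array([uniq[e] for e in self.elements])

    def transformed(self, rotation=None, translation=None) -> "StructureFrame":
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation).T
        if translation is not None:
            xyz = xyz + np.asarray(translation)
        return StructureFrame(self.chains, self.resnums, self.resnames,
                              self.atom_names, self.elements, xyz,
                              self.model_index)


@dataclass(frozen=True)
class ResiduePairSpec:
    """A labelled inter-site distance: one atom on each of two chains."""

    label: str
    chain_a: str
    resnum_a: int
    chain_b: str
    resnum_b: int
    atom: str = "CA"


def read_structure_frames(path) -> list:
    """Read a PDB/mmCIF file; each model becomes one StructureFrame."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    frames = []
    for mi, model in enumerate(st):
        chains, resnums, resnames, names, elements, coords = [], [], [], [], [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    chains.append(chain.name)
                    resnums.append(residue.seqid.num)
                    resnames.append(residue.name)
                    names.append(atom.name)
                    elements.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        frames.append(StructureFrame(
            np.array(chains), np.array(resnums, dtype=int), np.array(resnames),
            np.array(names), np.array(elements), np.array(coords),
            model_index=mi))
    return frames


def write_pdb(path, frames) -> None:
    """Write frames as a multi-model PDB file."""
    import gemmi

    st = gemmi.Structure()
    st.name = "frames"
    for frame in frames:
        model = gemmi.Model(str(frame.model_index + 1))
        for cname in pd.unique(frame.chains):
            chain = gemmi.Chain(str(cname))
            sel = np.flatnonzero(frame.chains == cname)
            for rnum in pd.unique(frame.resnums[sel]):
                rsel = sel[frame.resnums[sel] == rnum]
                res = gemmi.Residue()
                res.seqid = gemmi.SeqId(int(rnum), " ")
                res.name = str(frame.resnames[rsel[0]])
                for i in rsel:
                    atom = gemmi.Atom()
                    atom.name = str(frame.atom_names[i])
                    atom.element = gemmi.Element(str(frame.elements[i]))
                    atom.pos = gemmi.Position(*frame.coords[i])
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Distance metrics


def pair_distance(frame: StructureFrame, spec: ResiduePairSpec) -> float:
    """Euclidean distance between the two specified atoms (Å)."""
    a = frame.atom(spec.chain_a, spec.resnum_a, spec.atom)
    b = frame.atom(spec.chain_b, spec.resnum_b, spec.atom)
    return float(np.linalg.norm(a - b))


def clamshell_distance(frame: StructureFrame, chain: str,
                       res_upper: int = 144, res_lower: int = 272) -> float:
    """Cα–Cα distance between the upper- and lower-lobe reporter residues
    of one clamshell (defaults Tyr144–Ser272); small when the lobe is open,
    in the mGluR2 numbering convention."""
    a = frame.atom(chain, res_upper, "CA")
    b = frame.atom(chain, res_lower, "CA")
    return float(np.linalg.norm(a - b))


def _com(frame: StructureFrame, idx: np.ndarray, mass_weighted: bool) -> np.ndarray:
    if idx.size == 0:
        raise ValueError("empty selection")
    xyz = frame.coords[idx]
    if mass_weighted:
        m = frame.masses()[idx]
        return (xyz * m[:, None]).sum(axis=0) / m.sum()
    return xyz.mean(axis=0)


def lobe_separation(frame: StructureFrame, chains=("A", "B"),
                    residue_ranges=((188, 317), (452, 474)),
                    mass_weighted: bool = True) -> float:
    """Distance between the centers of mass of the two lower lobes.

    Each lobe is the union of the given residue ranges (inclusive) on one
    chain; mass weighting uses standard atomic masses, or unit masses when
    ``mass_weighted=False`` (convenient for toy point clouds).
    """
    sel_resnums = []
    for lo, hi in residue_ranges:
        sel_resnums.extend(range(lo, hi + 1))
    coms = []
    for chain in chains:
        idx = frame.select(chain=chain, resnums=sel_resnums)
        coms.append(_com(frame, idx, mass_weighted))
    return float(np.linalg.norm(coms[0] - coms[1]))


# ---------------------------------------------------------------------------
# Hydrogen bonds


def hbond_present(donor_xyz, hydrogen_xyz, acceptor_xyz,
                  distance_cutoff: float = 3.5,
                  angle_cutoff_deg: float = 50.0) -> bool:
    """Geometric hydrogen-bond test for one D–H···A triplet.

    Present iff the donor–acceptor distance is ≤ ``distance_cutoff`` Å and
    the deviation of the D–H···A arrangement from linearity is ≤
    ``angle_cutoff_deg`` degrees (the convention of common trajectory
    analysis tools; configurable).
    """
    d = np.asarray(donor_xyz, float)
    h = np.asarray(hydrogen_xyz, float)
    a = np.asarray(acceptor_xyz, float)
    if np.linalg.norm(d - a) > distance_cutoff:
        return False
    v1 = d - h
    v2 = a - h
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate D–H···A geometry")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    dha = np.degrees(np.arccos(cosang))      # 180° = perfectly linear
    return bool(180.0 - dha <= angle_cutoff_deg)


def any_hbond(triplets, distance_cutoff: float = 3.5,
              angle_cutoff_deg: float = 50.0) -> bool:
    """Residue–residue contact: present if any candidate triplet qualifies."""
    return any(hbond_present(d, h, a, distance_cutoff, angle_cutoff_deg)
               for d, h, a in triplets)


# ---------------------------------------------------------------------------
# Superposition, RMSF, helix angle


def _kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rotation+translation mapping mobile onto target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    return rot, tc - rot @ mc


def window_rmsf(frames, chain: str, align_residues=((155, 166), (180, 188)),
                rmsf_residues=(166, 180), reference: StructureFrame | None = None
                ) -> pd.DataFrame:
    """Per-residue Cα RMSF after rigid superposition on flanking segments.

    Frames are superposed on the Cα atoms of the alignment ranges
    (inclusive); by default against the mean structure, computed by a first
    alignment pass to frame 0 (or to ``reference`` when supplied).  RMSF is
    the root-mean-square deviation of each Cα in the target range from its
    time-averaged position.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames for an RMSF")
    align_resnums = []
    for lo, hi in align_residues:
        align_resnums.extend(range(lo, hi + 1))
    idx_align = frames[0].select(chain=chain, resnums=align_resnums,
                                 atom_name="CA")
    if idx_align.size < 3:
        raise ValueError("alignment selection needs at least 3 Cα atoms")
    lo, hi = rmsf_residues
    idx_rmsf = frames[0].select(chain=chain, resnums=range(lo, hi + 1),
                                atom_name="CA")

    def aligned_coords(target_align):
        out = np.empty((len(frames), idx_rmsf.size, 3))
        for i, fr in enumerate(frames):
            rot, trans = _kabsch(fr.coords[idx_align], target_align)
            out[i] = fr.coords[idx_rmsf] @ rot.T + trans
        return out

    if reference is None:
        first_pass = aligned_coords(frames[0].coords[idx_align])
        # mean positions of the alignment atoms after the first pass
        ref_align = np.empty((len(frames), idx_align.size, 3))
        for i, fr in enumerate(frames):
            rot, trans = _kabsch(fr.coords[idx_align],
                                 frames[0].coords[idx_align])
            ref_align[i] = fr.coords[idx_align] @ rot.T + trans
        target = ref_align.mean(axis=0)
    else:
        target = reference.coords[idx_align]
    coords = aligned_coords(target)
    mean_pos = coords.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((coords - mean_pos) ** 2, axis=2), axis=0))
    resnums = frames[0].resnums[idx_rmsf]
    return pd.DataFrame({"resnum": resnums, "rmsf_A": rmsf})


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9 or (s.size > 1 and s[0] - s[1] < 1e-9 and s[1] > 0.99 * s[0]):
        raise ValueError("degenerate selection: no unique principal axis")
    axis = vt[0]
    # orient along increasing residue order (N→C direction)
    if (points[-1] - points[0]) @ axis < 0:
        axis = -axis
    return axis


def interhelix_angle(frame: StructureFrame, chain_a: str = "A",
                     chain_b: str = "B", residues=(95, 108),
                     directed: bool = True) -> float:
    """Angle between the principal axes of two helical Cα selections.

    Axes are the first principal components of each helix's Cα coordinates,
    oriented N→C.  ``directed=True`` reports the full [0°, 180°] angle
    (antiparallel helices → 180°); ``directed=False`` folds it to [0°, 90°].
    """
    lo, hi = residues
    sels = []
    for chain in (chain_a, chain_b):
        idx = frame.select(chain=chain, resnums=range(lo, hi + 1),
                           atom_name="CA")
        if idx.size < 4:
            raise ValueError(f"helix selection on chain {chain} has fewer "
                             "than 4 Cα atoms")
        sels.append(frame.coords[idx])
    a1 = _principal_axis(sels[0])
    a2 = _principal_axis(sels[1])
    cosang = np.clip(a1 @ a2, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    if not directed and angle > 90.0:
        angle = 180.0 - angle
    return angle


def metrics_table(frames, pair_specs) -> pd.DataFrame:
    """Tidy per-model table of labelled pair distances."""
    rows = []
    for frame in frames:
        for spec in pair_specs:
            rows.append({"model": frame.model_index, "metric": spec.label,
                         "value": pair_distance(frame, spec)})
    return pd.DataFrame(rows)
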