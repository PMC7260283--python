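"""Structural-ensemble observables: Cα distances, distance distributions,
rigid superposition and per-residue RMSF.

The analyses mirror how conformational mobility of the LeuT N-terminus is
quantified from simulation ensembles: distances from the Cα of each
N-terminal residue to a remote anchor residue (A335 on extracellular loop 4,
or H510 at the end of TM12), histograms of those distances over frames, and
root mean square fluctuations after superposition on a stable core.  All
lengths are carried in nm internally; PDB files are Å and converted at the
I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation


@dataclass
class StructuralEnsemble:
    """Frames × residues × 3 coordinates (nm) with residue identifiers.

    ``residue_ids`` are author residue numbers (1-based, as in R5, A335,
    H510); every frame holds the same residues in the same order.
    """

    frames: np.ndarray  # (n_frames, n_residues, 3), nm
    residue_ids: np.ndarray  # (n_residues,), int
    residue_names: tuple[str, ...] = ()
    labels: tuple[str, ...] = ()  # per-frame tags
    chain: str = "A"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_residues, 3)")
        if self.frames.shape[1] != self.residue_ids.size:
            raise ValueError("residue_ids length must match frame width")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in ensemble")
        if np.unique(self.residue_ids).size != self.residue_ids.size:
            raise ValueError("duplicate residue ids")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_residues(self) -> int:
        return self.frames.shape[1]

    def frame(self, index: int) -> np.ndarray:
        return self.frames[index]

    def index_of(self, residue_id: int) -> int:
        """Row index of an author residue number; raises if absent."""
        hits = np.nonzero(self.residue_ids == residue_id)[0]
        if hits.size == 0:
            raise KeyError(f"residue {residue_id} not in ensemble")
        return int(hits[0])


@dataclass
class DistanceDistribution:
    """Normalized histogram of a Cα–Cα distance over frames."""

    residue_id: int
    anchor_id: int
    bin_edges: np.ndarray  # nm
    densities: np.ndarray  # probability density per bin
    mean: float  # nm
    mode: float  # nm, center of maximal bin (ties -> lowest distance)
    sd: float  # nm


@dataclass
class RMSFProfile:
    residue_ids: np.ndarray
    rmsf: np.ndarray  # nm
    fit_selection: tuple[int, ...] = field(default_factory=tuple)


def read_ensemble(path, chain: str = "A", models=None) -> StructuralEnsemble:
    """Read a (multi-model) PDB file into a Cα ensemble.

    One frame per MODEL record (a single-structure file yields one frame);
    coordinates are converted Å → nm.  Where alternate locations exist the
    highest-occupancy one is kept.  Residues are indexed by author residue
    number; insertion codes are rejected.

    Parameters
    ----------
    models:
        Optional sequence of 0-based frame indices to keep.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(altloc="occupancy")
    mask = (stack.chain_id == chain) & (stack.atom_name == "CA")
    if not mask.any():
        present = sorted(set(stack.chain_id))
        raise KeyError(f"chain {chain!r} has no CA atoms; chains present: {present}")
    sub = stack[:, mask]
    if any(code.strip() for code in sub.ins_code):
        raise ValueError("insertion codes are not supported")
    res_ids = sub.res_id
    if np.unique(res_ids).size != res_ids.size:
        raise ValueError(f"duplicate CA atoms for a residue in chain {chain!r}")
    order = np.argsort(res_ids, kind="stable")
    coords = sub.coord[:, order, :] / 10.0  # Å -> nm
    ensemble = StructuralEnsemble(
        frames=coords,
        residue_ids=res_ids[order],
        residue_names=tuple(sub.res_name[order]),
        chain=chain,
    )
    if models is not None:
        idx = np.asarray(list(models), dtype=int)
        ensemble = StructuralEnsemble(
            frames=ensemble.frames[idx],
            residue_ids=ensemble.residue_ids,
            residue_names=ensemble.residue_names,
            chain=chain,
        )
    return ensemble


def ca_distance(
    ensemble: StructuralEnsemble, frame: int, res_i: int, res_j: int
) -> float:
    """Euclidean Cα–Cα distance (nm) between two residues in one frame."""
    coords = ensemble.frame(frame)
    a = coords[ensemble.index_of(res_i)]
    b = coords[ensemble.index_of(res_j)]
    return float(np.linalg.norm(a - b))


def distance_distributions(
    ensemble: StructuralEnsemble,
    targets,
    anchor: int,
    bin_width: float = 0.05,
) -> list[DistanceDistribution]:
    """Per-target histograms of distance-to-anchor over all frames.

    The default 0.05 nm bin width resolves ~0.1 nm features of the
    distributions without empty-bin noise at a few thousand frames.
    Mean and sd are the exact frame-wise statistics (not re-derived from
    the histogram); the mode is the center of the maximal bin, ties
    resolved toward the lowest distance.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("empty target list")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    anchor_xyz = ensemble.frames[:, ensemble.index_of(anchor), :]
    out = []
    for target in targets:
        d = np.linalg.norm(
            ensemble.frames[:, ensemble.index_of(target), :] - anchor_xyz, axis=1
        )
        lo = np.floor(d.min() / bin_width) * bin_width
        n_bins = max(1, int(np.ceil((d.max() - lo) / bin_width + 1e-12)))
        edges = lo + bin_width * np.arange(n_bins + 1)
        counts, edges = np.histogram(d, bins=edges)
        densities = counts / (counts.sum() * bin_width)
        mode_bin = int(np.argmax(counts))  # argmax takes the first maximum
        out.append(
            DistanceDistribution(
                residue_id=int(target),
                anchor_id=int(anchor),
                bin_edges=edges,
                densities=densities,
                mean=float(d.mean()),
                mode=float(0.5 * (edges[mode_bin] + edges[mode_bin + 1])),
                sd=float(d.std(ddof=0)),
            )
        )
    return out


def _select(frame: np.ndarray, residue_ids: np.ndarray, selection) -> np.ndarray:
    rows = [int(np.nonzero(residue_ids == rid)[0][0]) for rid in selection]
    return frame[rows]


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection=None,
    residue_ids=None,
):
    """Least-squares rigid superposition (Kabsch) of two frames.

    Parameters
    ----------
    mobile, reference:
        (n, 3) coordinate arrays in nm.
    selection:
        Optional residue ids to fit on; requires ``residue_ids`` giving
        the row labels of both frames.  Default: all rows.

    Returns
    -------
    (rotation, translation, rmsd):
        ``rotation @ mobile_row + translation`` maps mobile onto the
        reference frame; rotation is proper (det +1); rmsd is the
        post-fit value in nm over the fitted selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        if residue_ids is None:
            raise ValueError("selection requires residue_ids")
        residue_ids = np.asarray(residue_ids)
        mob = _select(mobile, residue_ids, selection)
        ref = _select(reference, residue_ids, selection)
    else:
        mob, ref = mobile, reference
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference selections must both be (n, 3)")
    if mob.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-10) < 2:
        raise ValueError("selected points are collinear")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    rotation = rot.as_matrix()
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    rmsd = float(rssd / np.sqrt(mob.shape[0]))
    return rotation, translation, rmsd


def rmsf(
    ensemble: StructuralEnsemble,
    fit_selection=None,
    measure_selection=None,
) -> RMSFProfile:
    """Per-residue root mean square fluctuation in nm.

    Every frame is superposed onto the first frame using ``fit_selection``
    before fluctuations about the ensemble-mean position are measured:
    RMSF_i = sqrt(<|r_i - <r_i>|^2>).  When ``fit_selection`` is None the
    residues outside ``measure_selection`` are used, matching the usual
    practice of fitting on the stable core while measuring the mobile
    region; if fewer than 3 such residues exist the frames are used as-is
    (appropriate for ensembles sampled in a fixed laboratory frame, such
    as anchored tether models).
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    if measure_selection is None:
        measure_selection = list(ensemble.residue_ids)
    else:
        measure_selection = list(measure_selection)
    if not measure_selection:
        raise ValueError("empty measure selection")
    if fit_selection is None:
        complement = [
            int(r) for r in ensemble.residue_ids if r not in set(measure_selection)
        ]
        fit_selection = complement if len(complement) >= 3 else []
    else:
        fit_selection = list(fit_selection)

    frames = ensemble.frames
    if fit_selection:
        aligned = np.empty_like(frames)
        aligned[0] = frames[0]
        for k in range(1, ensemble.n_frames):
            rot, trans, _ = superpose(
                frames[k], frames[0], fit_selection, ensemble.residue_ids
            )
            aligned[k] = frames[k] @ rot.T + trans
    else:
        aligned = frames

    rows = [ensemble.index_of(r) for r in measure_selection]
    sub = aligned[:, rows, :]
    dev = sub - sub.mean(axis=0, keepdims=True)
    values = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    return RMSFProfile(
        residue_ids=np.asarray(measure_selection, dtype=int),
        rmsf=values,
        fit_selection=tuple(int(r) for r in fit_selection),
    )
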