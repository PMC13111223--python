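"""Multi-subject synthetic cohorts with a known connectivity-anisotropy link.

All subjects share one slab head phantom (skin / cortical bone / CSF /
grey / white layers with a sponge-pad anode and cathode on opposite
faces) and a four-parcel atlas whose regions play the roles of the anode
area (P2), its contralateral partner (P1) and two control regions (C2,
AF3). Across subjects, the streamline count of the designated P2-P1 edge
and a white-matter anisotropy parameter are coupled with a controllable
strength and Gaussian noise, so the downstream correlation between
connectivity strength and field spread has a known population value:

    r = coupling / sqrt(coupling^2 + noise_sd^2)

``coupling_for_target_r`` inverts this to hit a requested design point
(e.g. r = 0.45).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import ParcelAtlas, Tractogram
from .grids import GREY_MATTER, WHITE_MATTER, LabeledVolume
from .phantoms import (ElectrodeSpec, attach_electrodes, make_fiber_tensor_field,
                       make_slab_phantom, make_toy_tractogram)
from .tensors import TensorField

#: designated atlas parcels; P2 is the anode-area analogue
PARCELS = {"P2": 1, "P1": 2, "C2": 3, "AF3": 4}

#: mean / sd of the designated P2-P1 streamline count across subjects
EDGE_MEAN = 150.0
EDGE_SD = 30.0

#: baseline counts for the remaining edges (jittered per subject)
BASE_COUNTS = {("P2", "C2"): 80, ("P2", "AF3"): 50, ("P1", "C2"): 30,
               ("P1", "AF3"): 40, ("C2", "AF3"): 20}

#: white-matter mean diffusivity, mm^2/s, and baseline eigenvalue ratio
WM_MD = 0.7e-3
BASE_RATIO = 3.0
RATIO_LOG_SCALE = 0.3


@dataclass
class SubjectBundle:
    """One synthetic participant: geometry, tensors, tractogram, truth."""

    subject_id: str
    labeled_volume: LabeledVolume
    diffusion_tensors: TensorField
    tractogram: Tractogram
    true_coupling: float
    seed: int
    anisotropy_param: float = 0.0  # latent variable coupled to the P2-P1 edge
    edge_weight: float = 0.0  # realized P2-P1 streamline count
    atlas: ParcelAtlas | None = None
    electrodes: list = field(default_factory=list)


def coupling_for_target_r(r: float, noise_sd: float) -> float:
    """Coupling giving population correlation ``r`` at the given noise."""
    if not 0 <= r < 1:
        raise ValueError("target r must lie in [0, 1)")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive for a finite target r")
    return r * noise_sd / np.sqrt(1.0 - r * r)


def cohort_phantom(spacing_mm: float = 1.0):
    """Shared 32 mm slab geometry, electrodes and 4-parcel atlas.

    Layer stack (bottom to top, z): skin 2, cortical bone 2, CSF 2, grey 4,
    white 12, grey 4, CSF 2, cortical bone 2, skin 2 mm. The anode sits on
    the +z face over parcel P2, the cathode on the -z face. Pads are desk
    scale (8 x 8 and 12 x 12 mm sponge+copper) so the field stays focal
    within the 32 mm cross-section.
    """
    layers = ["skin", "bone_cortical", "csf", "grey_matter", "white_matter",
              "grey_matter", "csf", "bone_cortical", "skin"]
    thick = [2, 2, 2, 4, 12, 4, 2, 2, 2]
    vol = make_slab_phantom(len(layers), layers, thick, (32.0, 32.0),
                            spacing_mm)
    anode = ElectrodeSpec("anode", (22.0, 16.0, 32.0), (0, 0, 1.0),
                          pad_size_mm=(8.0, 8.0), copper_thickness_mm=1.0,
                          sponge_thickness_mm=2.0, potential_V=1.0)
    cathode = ElectrodeSpec("cathode", (10.0, 16.0, 0.0), (0, 0, -1.0),
                            pad_size_mm=(12.0, 12.0), copper_thickness_mm=1.0,
                            sponge_thickness_mm=2.0, potential_V=-1.0)
    vol = attach_electrodes(vol, [anode, cathode])
    atlas_labels = np.zeros(vol.shape, dtype=np.int16)

    def box(x0, x1, y0, y1, z0, z1):
        idx = np.argwhere(np.ones(vol.shape, dtype=bool))
        c = vol.voxel_centers_world(idx)
        m = ((c[:, 0] > x0) & (c[:, 0] < x1) & (c[:, 1] > y0) & (c[:, 1] < y1)
             & (c[:, 2] > z0) & (c[:, 2] < z1))
        out = np.zeros(vol.shape, dtype=bool)
        out[tuple(idx[m].T)] = True
        return out

    gm = vol.labels == GREY_MATTER
    # top grey-matter band hosts P2 (right, under the anode) and P1 (left);
    # the bottom band hosts the control regions C2 and AF3
    atlas_labels[box(16, 28, 4, 28, 20, 26) & gm] = PARCELS["P2"]
    atlas_labels[box(4, 16, 4, 28, 20, 26) & gm] = PARCELS["P1"]
    atlas_labels[box(16, 28, 4, 28, 6, 12) & gm] = PARCELS["C2"]
    atlas_labels[box(4, 16, 4, 28, 6, 12) & gm] = PARCELS["AF3"]
    atlas = ParcelAtlas(
        atlas_labels, vol.affine,
        names={v: k for k, v in PARCELS.items()},
        hemisphere={PARCELS["P2"]: "right", PARCELS["C2"]: "right",
                    PARCELS["P1"]: "left", PARCELS["AF3"]: "left"},
    )
    return vol, [anode, cathode], atlas


def _subject_tensors(volume: LabeledVolume, anisotropy_param: float
                     ) -> TensorField:
    """Whole-WM fiber bundle along x (the P2->P1 direction).

    The longitudinal/transverse diffusivity ratio is
    1 + (BASE_RATIO - 1) * exp(RATIO_LOG_SCALE * anisotropy_param) at fixed
    mean diffusivity WM_MD — a smooth monotone map that stays above 1
    (tensor remains prolate along the bundle) for any parameter value.
    """
    ratio = 1.0 + (BASE_RATIO - 1.0) * np.exp(
        RATIO_LOG_SCALE * anisotropy_param)
    lam_t = 3.0 * WM_MD / (ratio + 2.0)
    lam_l = ratio * lam_t
    return make_fiber_tensor_field(
        volume,
        [{"principal_direction": (1.0, 0.0, 0.0),
          "eigenvalues": (lam_l, lam_t, lam_t)}],
    )


def make_cohort(n_subjects: int, coupling: float, noise_sd: float,
                seed: int, spacing_mm: float = 1.0) -> list:
    """Generate a cohort of SubjectBundle sharing one phantom geometry.

    Per subject, the P2-P1 streamline count w is drawn around EDGE_MEAN and
    the anisotropy parameter is
    t = coupling * (w - EDGE_MEAN)/EDGE_SD + noise_sd * z, z ~ N(0, 1),
    so corr(w, t) has expectation coupling/sqrt(coupling^2 + noise_sd^2)
    (exactly 1 when noise_sd = 0 and coupling > 0). Identical seeds give
    bit-identical cohorts; subject streams are derived from the master seed
    by fixed offsets, so truncating the cohort preserves the early subjects.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for a correlation cohort")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    volume, electrodes, atlas = cohort_phantom(spacing_mm)
    ids = PARCELS
    bundles = []
    for s in range(n_subjects):
        rng = np.random.default_rng([int(seed), s])
        w = max(1, int(round(EDGE_MEAN + EDGE_SD * rng.standard_normal())))
        w_std = (w - EDGE_MEAN) / EDGE_SD
        t = coupling * w_std + noise_sd * rng.standard_normal()
        counts = {(ids["P2"], ids["P1"]): w}
        for (a, b), c in BASE_COUNTS.items():
            jitter = int(round(3.0 * rng.standard_normal()))
            counts[(ids[a], ids[b])] = max(1, c + jitter)
        tract_seed = int((int(seed) * 1_000_003 + 7 * s + 1) % (2**31))
        tract = make_toy_tractogram(atlas, counts, seed=tract_seed)
        bundles.append(SubjectBundle(
            subject_id=f"sub-{s:02d}",
            labeled_volume=volume,
            diffusion_tensors=_subject_tensors(volume, t),
            tractogram=tract,
            true_coupling=coupling,
            seed=tract_seed,
            anisotropy_param=float(t),
            edge_weight=float(w),
            atlas=atlas,
            electrodes=electrodes,
        ))
    return bundles
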