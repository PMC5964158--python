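"""Shared fixtures: phantoms, segmentations and surfaces reused across files.

Everything heavy is session-scoped; the 2 mm pair is generated once and the
4 mm phantom once.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from repe import phantom, segreg, shaping
from repe.core import BinaryMask, Tissue


@pytest.fixture(scope="session")
def pair2():
    """Template/individual pair with known affine, 2 mm grid."""
    return phantom.default_individual(seed=3)


@pytest.fixture(scope="session")
def seg2(pair2):
    """Segmentation + registration of the 2 mm individual."""
    ibrain, iscalp = segreg.extract_brain_and_scalp(pair2.individual_intensity)
    template_brain = BinaryMask(
        pair2.template_labels.mask(Tissue.GRAY, Tissue.WHITE),
        pair2.template_labels.affine,
        role_tag="template_brain",
    )
    tm = segreg.fit_affine(ibrain, template_brain)
    return {"ibrain": ibrain, "iscalp": iscalp, "tm": tm}


@pytest.fixture(scope="session")
def surf2(seg2):
    return shaping.surface_from_mask(seg2["iscalp"])


@pytest.fixture(scope="session")
def icss2(pair2, seg2, surf2):
    ics = segreg.map_template_sulcus(pair2.template_sulcus, seg2["tm"])
    return shaping.project_to_scalp(ics, surf2)


@pytest.fixture(scope="session")
def phantom4():
    """Single individual phantom at 4 mm (fast field solves)."""
    grid = phantom.GridSpec((48, 48, 48), 4.0)
    vol, lab, truth = phantom.generate_head_phantom(seed=1, grid=grid)
    return {"vol": vol, "labels": lab, "truth": truth}


@pytest.fixture(scope="session")
def icss4(phantom4):
    iscalp = BinaryMask(
        phantom4["labels"].head_mask, phantom4["labels"].affine, "iScalp"
    )
    surf = shaping.surface_from_mask(iscalp)
    return shaping.project_to_scalp(phantom4["truth"].sulcus_gt, surf).dedupe()


@pytest.fixture(scope="session")
def sphere_mask4():
    """Voxelised 40 mm ball at 2 mm on a small grid."""
    g = phantom.GridSpec((52, 52, 52), 2.0)
    pts = g.world_points()
    ball = (np.linalg.norm(pts, axis=1) <= 40.0).reshape(g.shape)
    return BinaryMask(ball, g.affine, role_tag="ball")


@pytest.fixture(scope="session")
def sphere_surf4(sphere_mask4):
    return shaping.surface_from_mask(sphere_mask4)
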