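"""Shared fixtures: phantoms and pipeline runs reused across test modules.

Heavy end-to-end artifacts are session-scoped; small fixtures are generated
per test.  Everything is produced programmatically — no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import riblabel as rl


@pytest.fixture(scope="session")
def small_spec() -> rl.PhantomSpec:
    """A reduced in-plane phantom (192 px) with the full 12 rib pairs,
    bed and one clavicle-like distractor."""
    return rl.PhantomSpec(dims=(None, 192, 192))


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return rl.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_templates(small_spec):
    return rl.generate_template_set(small_spec, 15)


@pytest.fixture(scope="session")
def small_run(small_spec, small_phantom, small_templates):
    """Full IIP pipeline + sequence labeling on the reduced phantom."""
    vol, truth = small_phantom
    win = rl.apply_window(vol)
    mask = rl.build_iip_mask(win, small_templates)
    labels, report = rl.label_sequence(mask)
    return {"spec": small_spec, "vol": vol, "truth": truth, "win": win,
            "mask": mask, "labels": labels, "report": report}


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default 512x512 phantom (the study conditions)."""
    spec = rl.PhantomSpec()
    vol, truth = rl.generate_phantom(spec)
    templates = rl.generate_template_set(spec, 15)
    win = rl.apply_window(vol)
    mask = rl.build_iip_mask(win, templates)
    label_vol, clusters = rl.label_clusters(mask)
    labels, report = rl.label_sequence(mask)
    return {"spec": spec, "vol": vol, "truth": truth, "win": win,
            "templates": templates, "mask": mask,
            "cluster_label_volume": label_vol, "clusters": clusters,
            "labels": labels, "report": report}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
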