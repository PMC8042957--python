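"""Shared fixtures: validation-scale phantoms, built once per session."""

import numpy as np
import pytest

from microbic.phantom import PhantomConfig, build_phantom, sample_contact_map


@pytest.fixture(scope="session")
def small_cfg():
    """Validation-scale phantom geometry (5 grooves per side, 144x128x128)."""
    return PhantomConfig.validation_scale()


@pytest.fixture(scope="session")
def half_contact(small_cfg):
    """Phantom with a seeded ~50% contact map, plus its ground truth."""
    cm = sample_contact_map(0.5, seed=7, n_grooves=small_cfg.grooves_per_side_available)
    vol, gt = build_phantom(small_cfg, cm)
    return vol, gt, cm


@pytest.fixture(scope="session")
def full_contact(small_cfg):
    cm = sample_contact_map(1.0, seed=0, n_grooves=small_cfg.grooves_per_side_available)
    vol, gt = build_phantom(small_cfg, cm)
    return vol, gt, cm


@pytest.fixture(scope="session")
def ring_contact(small_cfg):
    """Rotationally symmetric pattern: odd grooves fully bonded, even grooves free."""
    n = small_cfg.grooves_per_side_available
    contact = np.zeros((n, 8), dtype=bool)
    contact[::2, :] = True
    from microbic.phantom import ContactMap

    cm = ContactMap(contact=contact, target_fraction=0.6, seed=0)
    vol, gt = build_phantom(small_cfg, cm)
    return vol, gt, cm
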