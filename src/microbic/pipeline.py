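"""End-to-end measurement: volume in, per-implant BIC out.

Chains axis estimation, multi-angle longitudinal reslicing, tri-class
segmentation, groove selection and contact probing, and the multi-angle
mean.  Also hosts the paired-modality simulation experiment used to study
how residual ceramic granules degrade the agreement between CT-measured BIC
and the prescribed ("histology") truth.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import bic as bic_mod
from . import phantom as phantom_mod
from .io import PipelineConfig, Volume
from .reslice import estimate_axis, extract_longitudinal_slice, implant_axial_range
from .segment import classify


def measure_volume(
    v: Volume,
    config: PipelineConfig | None = None,
) -> tuple[bic_mod.BICResult, list[bic_mod.BICResult]]:
    """Measure per-implant BIC on a volume at the configured angles.

    Returns the implant-level multi-angle mean result and the list of
    per-slice results (one per angle, in order).
    """
    config = config or PipelineConfig()
    seg_cfg = config.segmentation()
    meas_cfg = config.measurement()
    axis = estimate_axis(v, implant_threshold=config.implant_min)
    axial = implant_axial_range(v, axis, implant_threshold=config.implant_min)
    per_slice = []
    for a in config.angles_deg:
        angle = (a + config.angle_offset_deg) % 360.0
        sl = extract_longitudinal_slice(v, axis, angle, axial_range=axial)
        li = classify(sl, seg_cfg)
        profile = bic_mod.trace_implant_profile(li)
        grooves = bic_mod.select_grooves(profile, meas_cfg)
        per_slice.append(bic_mod.measure_bic(li, grooves, meas_cfg, angle_deg=a))
    return bic_mod.mean_bic(per_slice), per_slice


def paired_modality_experiment(
    n_implants: int = 6,
    target_fractions=None,
    base_config: phantom_mod.PhantomConfig | None = None,
    granule_count_mean: int = 0,
    granule_load_cv: float = 0.7,
    noise_sd: float = 5.0,
    angle_deg: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a batch of implants and measure CT BIC against prescribed truth.

    For each implant a contact map with its own target fraction is realised,
    the phantom is built, artifacts are added (noise always; granules when
    ``granule_count_mean > 0``, with a per-implant gamma-distributed load of
    coefficient of variation ``granule_load_cv`` — residual ceramic burden
    varies strongly between defects), and the 0-degree-plane BIC is measured.

    The prescribed per-plane BIC plays the role of the histology reading:
    granules are *excluded* from it by construction, while thresholded CT
    counts them as bone — the mechanism that decouples the two modalities.

    Returns a DataFrame with columns ``implant``, ``target_fraction``,
    ``bic_truth``, ``bic_uct``.
    """
    if target_fractions is None:
        target_fractions = np.linspace(0.25, 0.875, n_implants)
    base_config = base_config or phantom_mod.PhantomConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for i, tf in enumerate(target_fractions):
        # draw the same per-implant randomness whether or not granules are
        # used, so granule-free and granule batches share truths and noise
        # (a paired design)
        cfg = replace(base_config, noise_sd=noise_sd, seed=int(rng.integers(2**31 - 1)))
        shape = 1.0 / granule_load_cv**2
        load = rng.gamma(shape, max(granule_count_mean, 1) / shape)
        if granule_count_mean > 0:
            cfg = replace(cfg, granule_count=max(1, int(round(load))))
        cm = phantom_mod.sample_contact_map(
            float(tf),
            seed=int(rng.integers(2**31 - 1)),
            n_grooves=cfg.grooves_per_side_available,
        )
        vol, gt = phantom_mod.build_phantom(cfg, cm, angles=(angle_deg,))
        vol = phantom_mod.add_artifacts(vol, cfg)
        config = PipelineConfig(angles_deg=(angle_deg,))
        _, per_slice = measure_volume(vol, config)
        rows.append(
            {
                "implant": i,
                "target_fraction": float(tf),
                "bic_truth": gt.per_plane[angle_deg],
                "bic_uct": per_slice[0].per_slice_bic_percent,
            }
        )
    return pd.DataFrame(rows)
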