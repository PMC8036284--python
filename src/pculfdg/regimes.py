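"""Frozen generation regimes for synthetic nodule cohorts.

Two parameter regimes emulate the visual dichotomy of transformed PET
sequences. Malignant-like nodules are metabolically heterogeneous: several
uptake foci with at least three stacked amplitude levels whose positions
and amplitudes drift from slice to slice, so the outer contour changes
shape and the maximum emission jumps around. Benign-like nodules carry a
single stable focus: concentric contours, stationary maximum.

The numbers below are fixed; cohorts are reproducible from a seed alone.
Ranges are sampled uniformly per nodule.
"""

#: image geometry shared by all generated phantoms
GRID = {
    "grid_shape": (14, 64, 64),
    "in_plane_spacing_mm": 3.0,
    "slice_thickness_mm": 3.3,
    "background_activity": 0.6,
    "noise_sd": 0.03,
}

MALIGNANT_LIKE = {
    "label": "malignant",
    "radius_mm": (10.0, 14.0),
    "n_foci": (4, 5),
    # primary amplitude; secondary foci stacked by successive decay factors
    "amplitude": (5.0, 8.0),
    "amplitude_decay": (0.5, 0.8),
    "sigma_mm": (2.5, 3.5),
    "drift_mm": (1.5, 3.0),
    "amplitude_drift_frac": (0.15, 0.35),  # per-slice amplitude change, fraction of A
    "offset_frac": (0.35, 0.75),  # focus offset from nodule centre, fraction of radius
    "z_offset_frac": (0.2, 0.6),  # per-focus axial envelope offset, fraction of radius
    "z_sigma_frac": (0.15, 0.3),  # per-focus axial envelope width, fraction of radius
    "target_suvmax": (5.0, 12.0),
}

BENIGN_LIKE = {
    "label": "benign",
    "radius_mm": (8.0, 12.0),
    "n_foci": (1, 1),
    "amplitude": (4.0, 6.0),
    "amplitude_decay": (1.0, 1.0),
    "sigma_mm": (4.0, 6.0),
    "drift_mm": (0.0, 0.2),
    "amplitude_drift_frac": (0.0, 0.02),
    "offset_frac": (0.0, 0.1),
    "z_offset_frac": (0.0, 0.0),
    "z_sigma_frac": (0.5, 0.5),
    "target_suvmax": (3.5, 5.0),
}
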