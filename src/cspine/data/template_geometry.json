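{
  "version": "1.0",
  "units": "mm",
  "frame": "right-handed; +X anterior, +Y left (medio-lateral), +Z cranial; per-vertebra body frame origin at the vertebral body centre, axes aligned with the laboratory frame in the neutral position (foramen magnum horizontal, zero applied moment)",
  "note": "Synthetic anatomical template. The study this package emulates published no attachment or marker coordinates; these are anatomically plausible positions for an adult occipito-atlanto-axial complex. Ligament mechanics depend only on length changes, so absolute geometry is a free modelling choice.",
  "joint_centers_world": {
    "C0C1": [0.0, 0.0, 50.0],
    "C1C2": [0.0, 0.0, 30.0],
    "C2C3": [0.0, 0.0, 10.0]
  },
  "vertebrae": {
    "C0": {
      "origin_world": [0.0, 0.0, 60.0],
      "sagittal_reference_axis": [0.0, 1.0, 0.0],
      "markers_local": {
        "occ_post": [-55.0, 0.0, 2.0],
        "occ_left": [-30.0, 38.0, -2.0],
        "occ_right": [-30.0, -38.0, -2.0],
        "occ_ant": [10.0, 0.0, 8.0]
      },
      "attachments_local": {
        "basion": [3.0, 0.0, -7.0],
        "condyle_alar": [2.0, 9.0, -7.5],
        "cruciate_upper": [-6.0, 0.0, -8.0],
        "occ_collateral_upper": [5.0, 30.0, -6.0],
        "capsule01_upper_left": [5.0, 25.0, -9.0],
        "capsule01_upper_right": [5.0, -25.0, -9.0]
      }
    },
    "C1": {
      "origin_world": [0.0, 0.0, 40.0],
      "sagittal_reference_axis": [0.0, 1.0, 0.0],
      "markers_local": {
        "c1_post": [-40.0, 0.0, 0.0],
        "c1_left": [0.0, 45.0, 0.0],
        "c1_right": [0.0, -45.0, 0.0],
        "c1_ant": [15.0, 0.0, 2.0]
      },
      "attachments_local": {
        "all_upper": [16.0, 0.0, -6.0],
        "flavum12_upper": [-24.0, 0.0, -4.0],
        "interspinal12_upper": [-38.0, 0.0, -3.0],
        "itl12_upper_left": [0.0, 42.0, -4.0],
        "itl12_upper_right": [0.0, -42.0, -4.0],
        "aa_collateral_upper": [5.0, 30.0, -6.0],
        "occ_collateral_lower": [5.0, 30.0, 4.0],
        "capsule01_lower_left": [5.0, 25.0, 5.0],
        "capsule01_lower_right": [5.0, -25.0, 5.0],
        "capsule12_upper_left": [5.0, 28.0, -6.0],
        "capsule12_upper_right": [5.0, -28.0, -6.0]
      }
    },
    "C2": {
      "origin_world": [0.0, 0.0, 20.0],
      "sagittal_reference_axis": [0.0, 1.0, 0.0],
      "markers_local": {
        "c2_spin": [-45.0, 0.0, 2.0],
        "c2_left": [0.0, 40.0, 0.0],
        "c2_right": [0.0, -40.0, 0.0],
        "c2_dens": [8.0, 0.0, 10.0]
      },
      "attachments_local": {
        "dens_tip": [3.0, 0.0, 28.0],
        "dens_alar": [2.0, 0.0, 27.0],
        "cruciate_lower": [-6.0, 0.0, 20.0],
        "all_lower": [16.0, 0.0, 6.0],
        "pll_upper": [-10.0, 0.0, 4.0],
        "flavum12_lower": [-24.0, 0.0, 6.0],
        "flavum23_upper": [-24.0, 0.0, -4.0],
        "interspinal12_lower": [-38.0, 0.0, 7.0],
        "interspinal23_upper": [-40.0, 0.0, -3.0],
        "supraspinous_upper": [-46.0, 0.0, -2.0],
        "itl12_lower_left": [0.0, 40.0, 6.0],
        "itl12_lower_right": [0.0, -40.0, 6.0],
        "itl23_upper_left": [0.0, 40.0, -4.0],
        "itl23_upper_right": [0.0, -40.0, -4.0],
        "aa_collateral_lower": [5.0, 28.0, 6.0],
        "capsule12_lower_left": [5.0, 28.0, 7.0],
        "capsule12_lower_right": [5.0, -28.0, 7.0],
        "capsule23_upper_left": [-12.0, 24.0, -6.0],
        "capsule23_upper_right": [-12.0, -24.0, -6.0]
      }
    },
    "C3": {
      "origin_world": [0.0, 0.0, 0.0],
      "sagittal_reference_axis": [0.0, 1.0, 0.0],
      "markers_local": {
        "base_ant_left": [30.0, 30.0, -5.0],
        "base_ant_right": [30.0, -30.0, -5.0],
        "base_post_left": [-30.0, 30.0, -5.0],
        "base_post_right": [-30.0, -30.0, -5.0]
      },
      "attachments_local": {
        "pll_lower": [-10.0, 0.0, 6.0],
        "flavum23_lower": [-24.0, 0.0, 6.0],
        "interspinal23_lower": [-40.0, 0.0, 7.0],
        "supraspinous_lower": [-46.0, 0.0, 6.0],
        "itl23_lower_left": [0.0, 38.0, 6.0],
        "itl23_lower_right": [0.0, -38.0, 6.0],
        "capsule23_lower_left": [-12.0, 24.0, 6.0],
        "capsule23_lower_right": [-12.0, -24.0, 6.0]
      }
    }
  }
}
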