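# Versioned cell-parameter file: reduced morphologies and membrane constants
# for the three cell classes of the laminar gamma model.
#
# Geometry follows the Bush & Sejnowski-style reduced pyramidal morphology
# lineage. Apical lengths are scaled so that the summed apical-axis extent of
# the L5 pyramidal cell (102 + 463.92 + 463.92 + 305 = 1334.84 um) is exactly
# 2.21x that of the L2/3 pyramidal cell (60 + 306 + 238 = 604 um).
# z_projection is the signed length component along the apical (pia-directed)
# axis; the oblique dendrite runs parallel to the laminae (z = 0) and the two
# side basal dendrites descend at 45 degrees (z = -length / sqrt(2)).
#
# Maximal conductances are this package's calibrated values (the emergent
# network behaviour, not the absolute conductance set, is the validated
# surface); kinetic rate functions use canonical Traub/Mainen-lineage forms
# and are documented in docs/methods.md.
version: 1

reversal_potentials_mV:
  na: 50.0
  k: -90.0          # shared by fast K, Kdr, Km, KCa
  ca: 132.8
  h: -35.0
  ampa: 0.0
  gaba_a: -80.0

synapses:
  ampa:   {rise_tau_ms: 0.5, decay_tau_ms: 5.0, reversal_mV: 0.0}
  # AMPA onto fast-spiking interneurons is substantially faster than onto
  # pyramidal cells (GluA4-dominated receptors); used for all AMPA synapses
  # terminating on basket cells.
  ampa_on_inh: {rise_tau_ms: 0.5, decay_tau_ms: 2.5}
  # Exogenous rhythmic (burst) drive synapses: thalamocortical inputs with a
  # slower decay than local cortical AMPA.
  ampa_drive: {rise_tau_ms: 0.5, decay_tau_ms: 8.5}
  # Exogenous Poisson (background noise) drive synapses: slower still, a
  # lumped AMPA+NMDA-like conductance that sustains depolarization between
  # sparse events so the network rhythm is paced by inhibition rather than
  # by individual event arrivals.
  ampa_poisson: {rise_tau_ms: 0.5, decay_tau_ms: 9.0}
  gaba_a: {rise_tau_ms: 0.5, decay_tau_ms: 5.0, reversal_mV: -80.0}
  delivery_delay_ms: 1.0

# Tonic applied current: Table-style drive values are model-unit scalars;
# one drive unit corresponds to this many nA of somatic current.
i_app_unit_nA: 3.5

calcium:
  tau_ms: 20.0
  depth_um: 0.1
  rest_mM: 1.0e-4

spike_threshold_mV: 0.0
v_rest_init_mV: -65.0

cells:
  l23_pyramidal:
    cm_uF_cm2: 0.62
    axial_resistivity_ohm_cm: 200.0
    compartments:
      - {name: soma,           parent: null,         length_um: 22.1, diameter_um: 23.4, z_projection_um: 0.0}
      - {name: apical_trunk,   parent: soma,         length_um: 60.0, diameter_um: 4.25, z_projection_um: 60.0}
      - {name: apical_1,       parent: apical_trunk, length_um: 306.0, diameter_um: 4.08, z_projection_um: 306.0}
      - {name: apical_tuft,    parent: apical_1,     length_um: 238.0, diameter_um: 3.4,  z_projection_um: 238.0}
      - {name: apical_oblique, parent: apical_trunk, length_um: 340.0, diameter_um: 3.91, z_projection_um: 0.0}
      - {name: basal_1,        parent: soma,         length_um: 85.4,  diameter_um: 4.25, z_projection_um: -85.4}
      - {name: basal_2,        parent: basal_1,      length_um: 255.0, diameter_um: 2.72, z_projection_um: -180.312}
      - {name: basal_3,        parent: basal_1,      length_um: 255.0, diameter_um: 2.72, z_projection_um: -180.312}
    channels:        # maximal conductance densities, mS/cm^2, uniform unless overridden
      na:   {gbar_mS_cm2: 220.0}
      k:    {gbar_mS_cm2: 10.0}
      kdr:  {gbar_mS_cm2: 5.0}
      km:   {gbar_mS_cm2: 1.0}
      leak: {gbar_mS_cm2: 0.0426, reversal_mV: -66.0}

  l5_pyramidal:
    cm_uF_cm2: 0.85
    axial_resistivity_ohm_cm: 200.0
    compartments:
      - {name: soma,           parent: null,         length_um: 39.0,   diameter_um: 28.9, z_projection_um: 0.0}
      - {name: apical_trunk,   parent: soma,         length_um: 102.0,  diameter_um: 10.2, z_projection_um: 102.0}
      - {name: apical_1,       parent: apical_trunk, length_um: 463.92, diameter_um: 7.48, z_projection_um: 463.92}
      - {name: apical_2,       parent: apical_1,     length_um: 463.92, diameter_um: 4.93, z_projection_um: 463.92}
      - {name: apical_tuft,    parent: apical_2,     length_um: 305.0,  diameter_um: 3.4,  z_projection_um: 305.0}
      - {name: apical_oblique, parent: apical_trunk, length_um: 255.0,  diameter_um: 5.1,  z_projection_um: 0.0}
      - {name: basal_1,        parent: soma,         length_um: 85.0,   diameter_um: 6.8,  z_projection_um: -85.0}
      - {name: basal_2,        parent: basal_1,      length_um: 255.0,  diameter_um: 8.5,  z_projection_um: -180.312}
      - {name: basal_3,        parent: basal_1,      length_um: 255.0,  diameter_um: 8.5,  z_projection_um: -180.312}
    channels:
      na:   {gbar_mS_cm2: 250.0}
      k:    {gbar_mS_cm2: 20.0}
      kdr:  {gbar_mS_cm2: 10.0}
      km:   {gbar_mS_cm2: 2.0}
      ca:   {gbar_mS_cm2: 1.0}
      cat:  {gbar_mS_cm2: 2.0}
      h:    {gbar_mS_cm2: 0.15}
      kca:  {gbar_mS_cm2: 1.0}
      leak: {gbar_mS_cm2: 0.0426, reversal_mV: -67.0}
    # Dendritic Na is strongly reduced along the apical axis (weak backward
    # propagation of the somatic spike into the apical tree) while the
    # basal/oblique dendrites that receive proximal drive remain excitable.
    channel_overrides:
      apical_trunk:   {na: 40.0}
      apical_1:       {na: 40.0}
      apical_2:       {na: 40.0}
      apical_tuft:    {na: 40.0}
      apical_oblique: {na: 250.0}
      basal_1:        {na: 250.0}
      basal_2:        {na: 250.0}
      basal_3:        {na: 250.0}

  basket:
    cm_uF_cm2: 0.5
    axial_resistivity_ohm_cm: 200.0
    compartments:
      - {name: soma, parent: null, length_um: 15.0, diameter_um: 10.0, z_projection_um: 0.0}
    channels:
      na:   {gbar_mS_cm2: 300.0}
      k:    {gbar_mS_cm2: 90.0}
      leak: {gbar_mS_cm2: 0.1, reversal_mV: -65.0}
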