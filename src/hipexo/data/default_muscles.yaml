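# Reduced sagittal lower-limb muscle roster: nine branches per leg.
# Moment arms in metres, flexion-positive (ankle dorsiflexion positive);
# f_iso in newtons. Values are literature-plausible configuration defaults
# for a desk-scale model, not subject-specific claims.
muscles:
  - name: psoas            # mono-articular hip flexor
    arms: {hip: 0.045}
    f_iso: 1200.0
  - name: glut_max         # mono-articular hip extensor
    arms: {hip: -0.060}
    f_iso: 1900.0
  - name: rect_fem         # bi-articular hip flexor / knee extensor
    arms: {hip: 0.045, knee: -0.045}
    f_iso: 1200.0
  - name: semimem          # bi-articular hip extensor / knee flexor
    arms: {hip: -0.055, knee: 0.030}
    f_iso: 1500.0
  - name: vas_lat          # mono-articular knee extensor
    arms: {knee: -0.045}
    f_iso: 1870.0
  - name: bf_short         # short head: mono-articular knee flexor
    arms: {knee: 0.025}
    f_iso: 800.0
  - name: gas_med          # bi-articular knee flexor / ankle plantarflexor
    arms: {knee: 0.020, ankle: -0.040}
    f_iso: 1500.0
  - name: tib_ant          # mono-articular ankle dorsiflexor
    arms: {ankle: 0.035}
    f_iso: 900.0
  - name: soleus           # mono-articular ankle plantarflexor
    arms: {ankle: -0.045}
    f_iso: 3500.0
reserve_weight: 1.0   # N*m; small versus joint-moment scale => expensive
residual_weight: 1.0  # N*m; used only when residual slacks are enabled
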