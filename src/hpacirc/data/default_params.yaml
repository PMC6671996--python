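# Repository-default model parameters (rates per hour, concentrations a.u.).
#
# These are repository defaults, not experimental ground truth: they were
# chosen so that the light-entrained system oscillates with a 24 h period,
# free-runs in constant darkness with an intrinsic period of ~22 h, shows a
# clear-amplitude corticosterone rhythm, and the photic pathway delays the
# onset of light effects by 1-2 h.
parameters:
  k_p1: 1.22793     # CRH zero-order synthesis drive (conc/h); raised under chronic stress
  K_p1: 0.6         # hypothalamic feedback inhibition constant (conc)
  k_p2: 0.76745     # ACTH synthesis rate (1/h)
  K_p2: 1.0         # pituitary feedback inhibition constant (conc)
  k_p3: 0.76745     # adrenal sensitivity (1/h)
  V_d1: 0.89536     # CRH degradation Vmax (conc/h)
  K_d1: 0.3         # CRH degradation Km (conc)
  V_d2: 0.89536     # ACTH degradation Vmax (conc/h)
  K_d2: 0.3         # ACTH degradation Km (conc)
  V_d3: 0.89536     # CORT degradation Vmax (conc/h)
  K_d3: 0.3         # CORT degradation Km (conc)
  k_syn_GRm: 1.02327  # GR mRNA synthesis rate (conc/h)
  IC50_GRm: 0.5     # DR(N) level halving GR transcription (conc)
  k_deg: 1.02327    # GR mRNA degradation rate (1/h)
  k_syn_GR: 0.51164 # GR translation rate (1/h)
  k_deg_GR: 0.25582 # free GR degradation rate (1/h)
  k_on: 0.63955     # CORT-GR binding rate (1/(conc h))
  k_T: 0.25582      # DR nuclear translocation rate (1/h)
  k_re: 0.38373     # DR(N) recycling rate (1/h)
  r_f: 0.49         # recycled fraction of DR(N) efflux
  k_t: 2.0          # photic transfer-compartment rate (1/h); 3-stage delay ~1.5 h
  k_us: 0.8         # light_effect synthesis rate (1/h)
  K_M_us: 0.6       # phototransduction Hill half-max constant
  n: 4.0            # phototransduction Hill coefficient (ultrasensitive)
  k_deg_us: 0.5     # light_effect degradation rate (1/h)
  k_eff: 1.0        # degradation enhancement by the light-off chain
schedule:
  lights_on: 7.0
  lights_off: 21.0
  period: 24.0
  strength: 1.0
  overrides: []
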