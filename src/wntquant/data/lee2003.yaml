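# Reference rate constants and concentrations of the Wnt/beta-catenin
# reaction network of Lee et al. (2003), PLoS Biology 1(1):e10, Table 1
# ("reference state" of the Xenopus egg-extract model).
#
# Units: concentrations nM, time min.  First-order rates /min, second-order
# rates /nM/min, synthesis fluxes nM/min, dissociation constants nM.
#
# The four rapid binding steps (reactions 7, 8, 16 and 17) are specified in
# Lee 2003 only through their dissociation constants; the unreduced model
# integrated here needs explicit on/off rates.  `binding_forward_rate` sets
# the common forward (association) rate; each reverse rate is the forward
# rate times the corresponding K.  Results are insensitive to this choice
# over at least two orders of magnitude (see docs/methods.md).
k1: 0.182        # /min      Wnt-dependent Dsh activation (multiplied by W)
k2: 1.82e-2      # /min      Dsh inactivation
k3: 5.0e-2       # /nM/min   Dsh_a-mediated GSK3 release from APC/axin/GSK3
k4: 0.267        # /min      phosphorylation of the APC/axin/GSK3 complex
k5: 0.133        # /min      dephosphorylation of APC*/axin*/GSK3 (PP2A)
k6: 9.09e-2      # /nM/min   GSK3 binding to APC/axin
k_6: 0.909       # /min      GSK3 dissociation from APC/axin/GSK3
k9: 206.0        # /min      beta-catenin phosphorylation in the complex
k10: 206.0       # /min      release of phospho-beta-catenin from the complex
k11: 0.417       # /min      proteasomal degradation of phospho-beta-catenin
v12: 0.423       # nM/min    beta-catenin synthesis
k13: 2.57e-4     # /min      axin-independent beta-catenin degradation
v14: 8.22e-5     # nM/min    axin synthesis
k15: 0.167       # /min      axin degradation (free axin only)
K7: 50.0         # nM        dissociation constant, axin + APC
K8: 120.0        # nM        dissociation constant, beta-catenin + APC*/axin*/GSK3
K16: 30.0        # nM        dissociation constant, beta-catenin + TCF
K17: 1200.0      # nM        dissociation constant, beta-catenin + APC
binding_forward_rate: 100.0  # /nM/min
totals:                      # conserved totals of the reference state (nM)
  Dsh: 100.0
  TCF: 15.0
  GSK3: 50.0
  APC: 100.0
xenopus_initial:             # measured Xenopus egg-extract totals (nM)
  beta_catenin: 35.0
  axin: 0.02
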