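# Published physiological input parameters of the four SC injection sites.
# Units: v_site, v_lymph_capillary, v_node in L/kg body weight;
# q_sc as a fraction of cardiac output; l_aff as a fraction of total lymph
# flow; f_efferent as efferent/afferent flow ratio; n_nodes is the midpoint
# of the reported draining-node-count range.
arm:
  v_site: 0.00077
  q_sc: 0.00088
  l_aff: 0.00191
  v_lymph_capillary: 0.000352
  v_node: 0.000116
  n_nodes: 30.5
  f_vascular: 0.05
  f_endosomal: 0.0006
  f_interstitial: 0.595
  f_efferent: 0.93
abdomen:
  v_site: 0.00099
  q_sc: 0.00035
  l_aff: 0.00205
  v_lymph_capillary: 0.000392
  v_node: 8.38e-05
  n_nodes: 22.0
  f_vascular: 0.05
  f_endosomal: 0.0006
  f_interstitial: 0.595
  f_efferent: 0.93
back:
  v_site: 0.00115
  q_sc: 0.00105
  l_aff: 0.00262
  v_lymph_capillary: 0.000415
  v_node: 9.52e-05
  n_nodes: 24.5
  f_vascular: 0.05
  f_endosomal: 0.0006
  f_interstitial: 0.595
  f_efferent: 0.93
thigh:
  v_site: 0.00099
  q_sc: 0.00073
  l_aff: 0.00272
  v_lymph_capillary: 0.000387
  v_node: 8.38e-05
  n_nodes: 22.0
  f_vascular: 0.05
  f_endosomal: 0.0006
  f_interstitial: 0.595
  f_efferent: 0.93
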