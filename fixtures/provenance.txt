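Provenance of model inputs
==========================
Placeholder inputs (NOT from the published evaluation; replace before
drawing real-world conclusions):
  [synthetic] drug.price_per_administration = 580.0
  [synthetic] econ.horizon_max_age = 110.0
  [synthetic] indirect.workdays_lost_per_year_by_state.controlled = 0.5
  [synthetic] indirect.workdays_lost_per_year_by_state.death = 0.0
  [synthetic] indirect.workdays_lost_per_year_by_state.inadequate = 4.8
  [synthetic] indirect.workdays_lost_per_year_by_state.postop_controlled = 1.0
  [synthetic] indirect.workdays_lost_per_year_by_state.postop_uncontrolled = 4.8
  [synthetic] indirect.workdays_lost_per_year_by_state.surgery = 4.8
  [figure-only-placeholder] response.p_resp_wk24_bsc = 0.25
  [figure-only-placeholder] response.p_resp_wk24_dup = 0.6
  [figure-only-placeholder] response.p_resp_wk52_given_wk24_bsc = 0.7
  [figure-only-placeholder] response.p_resp_wk52_given_wk24_dup = 0.9

All remaining parameters are transcribed from published tables/text
or derived as complements; see the config provenance map.
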