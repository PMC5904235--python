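# Default inclusion/exclusion rules for the 2011-2012 observation window.
window_start: 2011-01-01
window_end: 2012-12-31
min_age: 50
require_resident: true
exclude_high_energy: true
exclude_pathological: true
strict_mechanism: false
unspecified_site_matches_both: true
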