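# Scale definitions for the psychosocial battery.
# columns: survey column names; item_min/item_max: admissible item range;
# cutoff: screening threshold on the total (null where no screen is defined).
pss:
  columns: [PSS01, PSS02, PSS03, PSS04, PSS05, PSS06, PSS07, PSS08, PSS09, PSS10]
  item_min: 0
  item_max: 4
  cutoff: null
phq9:
  columns: [PHQ01, PHQ02, PHQ03, PHQ04, PHQ05, PHQ06, PHQ07, PHQ08, PHQ09]
  item_min: 0
  item_max: 3
  cutoff: 15
gad7:
  columns: [GAD01, GAD02, GAD03, GAD04, GAD05, GAD06, GAD07]
  item_min: 0
  item_max: 3
  cutoff: 15
pcptsd:
  columns: [PTSD01, PTSD02, PTSD03, PTSD04, PTSD05]
  item_min: 0
  item_max: 1
  cutoff: 3
ssq:
  columns: [SSQ01, SSQ02, SSQ03, SSQ04, SSQ05]
  item_min: 0
  item_max: 5
  cutoff: null
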