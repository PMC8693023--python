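field,value
n_screened,155
n_failed_screen,32
severity_mild,23
severity_moderate,1
severity_moderately_severe,2
severity_severe,3
severity_profound,3
pathology_cerumen_impaction_ears,37
pathology_effusion,17
pathology_otitis_media,12
pathology_tympanic_retraction,8
pathology_dry_perforation,6
pathology_fungal_otitis_externa,2
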