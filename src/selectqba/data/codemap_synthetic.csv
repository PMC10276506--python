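# SYNTHETIC illustrative ICD-9-CM exposure code map, v1.
# Non-authoritative: prefixes chosen to be clinically plausible for each
# component so the pipeline and its tests run end to end.  Replace with a
# validated clinical code list for real analyses.  Poisoning components list
# unintentional external-cause prefixes only (the intent restriction is
# encoded here, not at runtime).
category,component,prefix
mental illness,depression,296.2
mental illness,depression,296.3
mental illness,depression,300.4
mental illness,depression,311
mental illness,anxiety,300.0
mental illness,anxiety,300.2
mental illness,anxiety,300.3
mental illness,PTSD,309.81
mental illness,bipolar,296.0
mental illness,bipolar,296.1
mental illness,bipolar,296.4
mental illness,bipolar,296.5
mental illness,bipolar,296.6
mental illness,bipolar,296.7
mental illness,bipolar,296.80
mental illness,bipolar,296.89
mental illness,schizophrenia,295
substance use,alcohol use disorder/poisoning,303
substance use,alcohol use disorder/poisoning,305.0
substance use,alcohol use disorder/poisoning,980.0
substance use,alcohol use disorder/poisoning,E860.0
substance use,alcohol use disorder/poisoning,E860.1
substance use,drug use disorder/poisoning,304
substance use,drug use disorder/poisoning,305.2
substance use,drug use disorder/poisoning,305.3
substance use,drug use disorder/poisoning,305.4
substance use,drug use disorder/poisoning,305.5
substance use,drug use disorder/poisoning,305.6
substance use,drug use disorder/poisoning,305.7
substance use,drug use disorder/poisoning,305.8
substance use,drug use disorder/poisoning,305.9
substance use,drug use disorder/poisoning,E850
substance use,drug use disorder/poisoning,E851
substance use,drug use disorder/poisoning,E852
substance use,drug use disorder/poisoning,E853
substance use,drug use disorder/poisoning,E854
substance use,drug use disorder/poisoning,E855
substance use,drug use disorder/poisoning,E858
substance use,opioid use disorder/poisoning,304.0
substance use,opioid use disorder/poisoning,304.7
substance use,opioid use disorder/poisoning,305.5
substance use,opioid use disorder/poisoning,965.00
substance use,opioid use disorder/poisoning,965.01
substance use,opioid use disorder/poisoning,965.02
substance use,opioid use disorder/poisoning,E850.0
substance use,opioid use disorder/poisoning,E850.1
substance use,opioid use disorder/poisoning,E850.2
substance use,sedative/hypnotic/anxiolytic use disorder/poisoning,304.1
substance use,sedative/hypnotic/anxiolytic use disorder/poisoning,305.4
substance use,sedative/hypnotic/anxiolytic use disorder/poisoning,E851
substance use,sedative/hypnotic/anxiolytic use disorder/poisoning,E852
substance use,sedative/hypnotic/anxiolytic use disorder/poisoning,E853.2
substance use,cannabis use disorder,304.3
substance use,cannabis use disorder,305.2
substance use,stimulant use disorder/poisoning,304.2
substance use,stimulant use disorder/poisoning,304.4
substance use,stimulant use disorder/poisoning,305.6
substance use,stimulant use disorder/poisoning,305.7
substance use,stimulant use disorder/poisoning,E854.2
substance use,stimulant use disorder/poisoning,E854.3
pain,rheumatoid arthritis/osteoarthritis,714
pain,rheumatoid arthritis/osteoarthritis,715
pain,migraine/chronic headache,346
pain,migraine/chronic headache,784.0
pain,fibromyalgia/chronic pain/fatigue,729.1
pain,fibromyalgia/chronic pain/fatigue,338.2
pain,fibromyalgia/chronic pain/fatigue,338.4
pain,fibromyalgia/chronic pain/fatigue,780.71
chronic disease,acute MI,410
chronic disease,heart failure,428
chronic disease,hypertension,401
chronic disease,hypertension,402
chronic disease,hypertension,403
chronic disease,hypertension,404
chronic disease,hypertension,405
chronic disease,stroke/TIA,433
chronic disease,stroke/TIA,434
chronic disease,stroke/TIA,435
chronic disease,stroke/TIA,436
chronic disease,asthma,493
chronic disease,COPD,490
chronic disease,COPD,491
chronic disease,COPD,492
chronic disease,COPD,496
chronic disease,diabetes,250
chronic disease,TBI,850
chronic disease,TBI,851
chronic disease,TBI,852
chronic disease,TBI,853
chronic disease,TBI,854
chronic disease,epilepsy,345
chronic disease,cancer,153
chronic disease,cancer,154
chronic disease,cancer,162
chronic disease,cancer,174
chronic disease,cancer,182
chronic disease,cancer,185
assault,,E960
assault,,E961
assault,,E962
assault,,E963
assault,,E965
assault,,E966
assault,,E967
assault,,E968
suicidal ideation/attempt,ideation,V62.84
suicidal ideation/attempt,attempt,E950
suicidal ideation/attempt,attempt,E951
suicidal ideation/attempt,attempt,E952
suicidal ideation/attempt,attempt,E953
suicidal ideation/attempt,attempt,E954
suicidal ideation/attempt,attempt,E955
suicidal ideation/attempt,attempt,E956
suicidal ideation/attempt,attempt,E957
suicidal ideation/attempt,attempt,E958
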