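prefix,category
250,Diabetes mellitus
272,Disorders of lipid metabolism
290,Dementia
294,Dementia
296,Mood disorders
300,Anxiety disorders
311,Mood disorders
331,Dementia
332,Parkinson disease
345,Epilepsy
349,Other nervous system disorders
401,Essential hypertension
402,Hypertension with complications
410,Acute myocardial infarction
414,Coronary atherosclerosis
427,Cardiac dysrhythmias
428,Congestive heart failure
433,Acute cerebrovascular disease
434,Acute cerebrovascular disease
435,Transient cerebral ischemia
438,Late effects of cerebrovascular disease
466,Acute bronchitis
536,Other gastrointestinal disorders
599,Urinary tract infection
715,Osteoarthritis
721,Spondylosis
724,Back problems
780,Other nervous system disorders
787,Other gastrointestinal disorders
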