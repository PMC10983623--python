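item,content,mean,sd,expected_influence_printed,predictability_printed
MBI1,Exhausted,2.63,1.5,0.501,0.749
MBI2,Used up,2.82,0.59,0.462,0.786
MBI3,Tired,2.39,1.55,0.528,0.721
MBI4,Stressed,2.36,1.55,0.454,0.793
MBI5,Breakdown,1.83,0.43,0.552,0.695
MBI6,Less interested,1.73,0.47,0.462,0.787
MBI7,Less enthusiastic,1.7,0.51,0.477,0.772
MBI8,Doubt significance,1.45,0.52,0.451,0.796
MBI9,Indifferent,1.45,0.51,0.47,0.778
MBI10,Effective,2.42,1.61,0.618,0.617
MBI11,Contributing,2.34,1.05,0.55,0.697
MBI12,Good at job,2.22,1.14,0.637,0.594
MBI13,Happy,2.24,1.08,0.523,0.726
MBI14,Worthwhile,2.39,1.1,0.532,0.717
MBI15,Confident,2.21,1.58,0.579,0.665
PHQ1,Anhedonia,0.86,0.45,0.521,0.728
PHQ2,Sad mood,0.79,0.36,0.577,0.666
PHQ3,Sleep,1.1,0.41,0.728,0.469
PHQ4,Fatigue,1.06,0.39,0.58,0.663
PHQ5,Appetite,0.85,0.28,0.652,0.575
PHQ6,Guilty,0.65,0.31,0.568,0.676
PHQ7,Concentration,0.73,0.42,0.622,0.613
PHQ8,Motor,0.54,0.28,0.617,0.619
PHQ9,Suicide,0.2,0.13,0.905,0.28
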