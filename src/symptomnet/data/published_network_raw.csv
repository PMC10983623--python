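,MBI1,MBI2,MBI3,MBI4,MBI5,MBI6,MBI7,MBI8,MBI9,MBI10,MBI11,MBI12,MBI13,MBI14,MBI15,PHQ1,PHQ2,PHQ3,PHQ4,PHQ5,PHQ6,PHQ7,PHQ8,PHQ9
MBI1,0.000,0.406,0.096,0.058,0.000,0.000,0.000,0.000,0.000,0.000,0.020,0.000,0.017,0.124,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
MBI2,0.041,0.000,0.153,0.059,0.000,0.000,0.000,0.000,0.000,0.226,0.073,0.000,0.028,0.000,0.129,0.000,0.000,0.000,0.117,0.000,0.000,0.000,0.000,0.000
MBI3,0.096,0.153,0.000,0.386,0.110,0.020,0.000,0.000,0.000,0.024,0.000,0.000,0.022,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
MBI4,0.058,0.059,0.386,0.000,0.362,0.054,0.000,0.000,0.000,0.019,0.000,0.000,0.000,0.000,0.087,0.000,0.000,0.022,0.000,0.000,0.000,0.000,0.000,0.000
MBI5,0.000,0.000,0.110,0.362,0.000,0.025,0.000,0.175,0.000,0.000,0.079,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.070,0.000,0.000,0.000,0.031,0.028
MBI6,0.000,0.000,0.020,0.054,0.025,0.000,0.447,0.023,0.102,0.000,0.000,0.146,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
MBI7,0.000,0.000,0.000,0.000,0.000,0.447,0.000,0.179,0.217,0.000,0.028,0.000,0.037,0.000,0.000,0.090,0.000,0.000,0.000,0.000,0.000,0.024,0.000,0.000
MBI8,0.000,0.000,0.000,0.000,0.175,0.023,0.179,0.000,0.460,0.000,0.000,0.000,0.015,0.000,0.000,0.020,0.000,0.025,0.000,0.000,0.000,0.062,0.000,0.000
MBI9,0.000,0.000,0.000,0.000,0.000,0.102,0.217,0.460,0.000,0.000,0.000,0.000,0.026,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
MBI10,0.000,0.226,0.024,0.019,0.000,0.000,0.000,0.000,0.000,0.000,0.231,0.000,0.000,0.048,0.065,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
MBI11,0.020,0.073,0.000,0.000,0.079,0.000,0.028,0.000,0.000,0.231,0.000,0.104,0.169,0.085,0.056,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000
MBI12,0.000,0.000,0.000,0.000,0.000,0.146,0.000,0.000,0.000,0.000,0.104,0.000,0.122,0.230,0.000,0.000,0.000,0.000,0.000,0.000,0.022,0.000,0.000,0.000
MBI13,0.017,0.028,0.022,0.000,0.000,0.000,0.037,0.015,0.026,0.000,0.169,0.122,0.000,0.165,0.195,0.000,0.000,0.000,0.012,0.000,0.000,0.000,0.000,0.000
MBI14,0.124,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.048,0.085,0.230,0.165,0.000,0.208,0.000,0.037,0.000,0.000,0.000,0.000,0.000,0.000,0.000
MBI15,0.000,0.129,0.000,0.087,0.000,0.000,0.000,0.000,0.000,0.065,0.056,0.000,0.195,0.208,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.025,0.014
PHQ1,0.000,0.000,0.000,0.000,0.000,0.000,0.090,0.020,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.381,0.000,0.297,0.083,0.000,0.069,0.000,0.000
PHQ2,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.037,0.000,0.381,0.000,0.107,0.000,0.000,0.288,0.000,0.050,0.000
PHQ3,0.000,0.000,0.000,0.022,0.000,0.000,0.000,0.025,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.107,0.000,0.192,0.206,0.000,0.000,0.000,0.000
PHQ4,0.000,0.117,0.000,0.000,0.070,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.012,0.000,0.000,0.297,0.000,0.192,0.000,0.189,0.000,0.093,0.000,0.000
PHQ5,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.083,0.000,0.206,0.189,0.000,0.066,0.040,0.162,0.000
PHQ6,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.022,0.000,0.000,0.000,0.000,0.288,0.000,0.000,0.066,0.000,0.211,0.262,0.164
PHQ7,0.000,0.000,0.000,0.000,0.000,0.000,0.024,0.062,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.069,0.000,0.000,0.093,0.040,0.211,0.000,0.293,0.000
PHQ8,0.000,0.000,0.000,0.000,0.031,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.025,0.000,0.050,0.000,0.000,0.162,0.262,0.293,0.000,0.072
PHQ9,0.000,0.000,0.000,0.000,0.028,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.014,0.000,0.000,0.000,0.000,0.000,0.164,0.000,0.072,0.000
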