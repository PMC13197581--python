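site,Ricketts Point,Williamstown,Jawbone,Altona,Kirk Point,Avalon,Point Henry,Grand Scenic,Point Richards,Edwards Point,North Swan Bay,South Swan Bay,Point Lonsdale,Mud Islands,Blairgowrie,Rosebud
Ricketts Point,0.0,0.021,0.055,0.03,0.036,0.065,0.052,0.067,0.033,0.056,0.068,0.071,0.219,0.085,0.08,0.036
Williamstown,0.021,0.0,0.05,0.028,0.039,0.068,0.066,0.062,0.049,0.061,0.092,0.078,0.182,0.083,0.082,0.031
Jawbone,0.055,0.05,0.0,0.079,0.044,0.056,0.067,0.055,0.04,0.071,0.093,0.092,0.19,0.05,0.08,0.039
Altona,0.03,0.028,0.079,0.0,0.032,0.087,0.055,0.08,0.07,0.063,0.082,0.08,0.181,0.099,0.093,0.051
Kirk Point,0.036,0.039,0.044,0.032,0.0,0.034,0.012,0.024,0.015,0.029,0.061,0.037,0.161,0.047,0.071,0.031
Avalon,0.065,0.068,0.056,0.087,0.034,0.0,0.017,0.003,0.016,0.072,0.073,0.053,0.174,0.036,0.062,0.03
Point Henry,0.052,0.066,0.067,0.055,0.012,0.017,0.0,0.015,0.018,0.073,0.065,0.055,0.196,0.056,0.093,0.047
Grand Scenic,0.067,0.062,0.055,0.08,0.024,0.003,0.015,0.0,0.01,0.056,0.063,0.052,0.165,0.042,0.073,0.034
Point Richards,0.033,0.049,0.04,0.07,0.015,0.016,0.018,0.01,0.0,0.052,0.06,0.044,0.163,0.033,0.062,0.019
Edwards Point,0.056,0.061,0.071,0.063,0.029,0.072,0.073,0.056,0.052,0.0,0.08,0.078,0.122,0.053,0.092,0.046
North Swan Bay,0.068,0.092,0.093,0.082,0.061,0.073,0.065,0.063,0.06,0.08,0.0,0.023,0.154,0.073,0.09,0.056
South Swan Bay,0.071,0.078,0.092,0.08,0.037,0.053,0.055,0.052,0.044,0.078,0.023,0.0,0.125,0.054,0.079,0.043
Point Lonsdale,0.219,0.182,0.19,0.181,0.161,0.174,0.196,0.165,0.163,0.122,0.154,0.125,0.0,0.138,0.18,0.15
Mud Islands,0.085,0.083,0.05,0.099,0.047,0.036,0.056,0.042,0.033,0.053,0.073,0.054,0.138,0.0,0.066,0.027
Blairgowrie,0.08,0.082,0.08,0.093,0.071,0.062,0.093,0.073,0.062,0.092,0.09,0.079,0.18,0.066,0.0,0.018
Rosebud,0.036,0.031,0.039,0.051,0.031,0.03,0.047,0.034,0.019,0.046,0.056,0.043,0.15,0.027,0.018,0.0
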