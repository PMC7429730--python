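dimension,measure,estimate,ui_lower,ui_upper
economic_status,D,54.15,49.59,58.70
economic_status,PAF,43.52,40.12,46.92
economic_status,PAR,26.74,24.65,28.83
economic_status,R,2.59,2.29,2.88
education,D,43.41,39.65,47.17
education,PAF,32.38,29.53,35.23
education,PAR,19.89,18.14,21.64
education,R,2.14,1.96,2.32
residence,D,34.35,30.47,38.22
residence,PAF,20.04,17.70,22.38
residence,PAR,12.31,10.88,13.75
residence,R,1.87,1.71,2.02
region,D,51.70,43.56,59.85
region,PAF,35.45,29.91,40.99
region,PAR,21.78,18.38,25.18
region,R,2.64,2.01,3.26
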