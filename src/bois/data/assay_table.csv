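receptor,ligand,g_alpha_max,g_alpha_log_ec50,barr_max,barr_log_ec50
adrenergic,Form,1.05,-9.62,1.02,-8.61
adrenergic,Iso,0.87,-9.71,0.94,-8.14
adrenergic,Fen,0.80,-9.41,0.94,-7.81
adrenergic,Epi,0.88,-9.01,0.69,-7.25
adrenergic,Salb,0.92,-8.30,0.33,X
adrenergic,Salm,0.97,-8.26,0.33,X
adrenergic,Clen,1.00,-8.85,0.17,X
adrenergic,Norepi,0.96,-6.84,0.21,X
adrenergic,Dob,0.94,-6.57,0.04,X
adrenergic,Pind,0.10,X,0.01,X
angiotensin,TRV120056,0.95,-7.34,1.00,-6.42
angiotensin,TRV120055,1.00,-7.97,1.03,-7.05
angiotensin,AngII,1.00,-8.84,1.00,-7.90
angiotensin,S1C4,0.93,-8.84,0.70,-6.66
angiotensin,A1,0.98,-8.52,0.95,-7.68
angiotensin,TRV120034,0.12,X,0.89,-7.68
angiotensin,TRV120026,0.09,X,0.89,-6.64
angiotensin,TRV120045,0.11,X,0.89,-7.57
angiotensin,SGG,0.17,X,0.72,-5.69
angiotensin,TRV120044,0.09,X,0.76,-6.79
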