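# Phaser log-likelihood-gain (LLG) scores for the 13 CASP10 refinement
# targets solved by X-ray crystallography with structure factors available:
# the released starting model and the best submitted prediction per target.
# Columns: target, starting_llg, best_model_id, best_llg
TR644	146.95	TR644TS124_1	275.13
TR663	43.31	TR663TS085_2	80.10
TR671	47.29	TR671TS479_4	60.23
TR674	96.42	TR674TS028_1	174.63
TR679	29.68	TR679TS197_2	54.35
TR681	392.24	TR681TS473_3	891.81
TR688	162.88	TR688TS049_2	193.26
TR689	914.95	TR689TS108_4	1097.58
TR704	62.07	TR704TS284_4	103.99
TR705	62.06	TR705TS473_1	68.55
TR712	910.16	TR712TS049_3	1127.80
TR747	51.40	TR747TS165_2	71.51
TR752	116.31	TR752TS197_4	181.24
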