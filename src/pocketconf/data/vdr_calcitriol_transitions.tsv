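system	state	lambda_nm	f	mu_tr_D	assignment	character	percent	predominant
calcitriol	1	266.9	0.5465	4.7610	H -> L	ICT	98	True
TRP286	9	196.3	0.4442	3.8620	H -> L+10	ICT	42	True
TYR295	11	177.4	0.3142	2.0488	H-2 -> L+3	ICT	36	True
TRP286-TYR295	30	179.9	0.5140	3.8191	H-5 -> L+8	ECT	33	True
calcitriol-TRP286	2	269.4	0.4954	3.6932	H -> L+1	ICT,ECT	84	True
calcitriol-TYR295	2	268.0	0.4985	4.1706	H -> L	ICT,ECT	46	True
calcitriol-TRP286-TYR295	3	270.5	0.4545	2.2506	H -> L+2	ECT,ICT	61	True
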