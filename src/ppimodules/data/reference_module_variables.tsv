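method	tier	module_id	n	n_ex	ex_mean	cor_mean	mf_mean	bp_mean	cc_mean
CPM	High	Int-2	5	5	8.33	0.22	0.76	0.7	0.7
CPM	High	Int-3	5	1	8.54	NA	0.85	0.88	0.84
CPM	High	Int-4	9	7	9.56	0.43	0.7	0.81	0.92
CPM	High	Int-7	17	13	8.88	0.17	0.63	0.58	0.66
CPM	High	Lit-2	5	5	8.33	0.22	0.76	0.7	0.7
CPM	High	Lit-5	9	9	9.62	0.42	0.59	0.68	0.66
CPM	High	Lit-9	8	8	9.02	0.62	0.85	0.92	0.82
CPM	High	Lit-11	10	9	8.17	0.3	0.58	0.74	0.61
CPM	High	Ortho-8	15	11	8.9	0.15	0.68	0.57	0.67
CPM	High	Ortho-12	10	9	10.73	0.59	0.83	1	0.98
CPM	Medium	Int-18	18	16	9.55	0.54	0.45	0.51	0.7
CPM	Medium	Ortho-18	17	15	9.65	0.58	0.49	0.6	0.72
CPM	Low	Int-13	13	11	8.79	0.39	0.45	0.73	0.96
CPM	Low	Lit-4	16	11	7.95	0.24	0.28	0.52	0.58
CPM	Low	Lit-14	11	10	8.79	0.39	0.4	0.72	0.95
CPM	Low	Ortho-7	8	7	9.48	0.41	0.48	0.56	0.61
MCODE	High	Int-5	9	7	9.56	0.43	0.7	0.81	0.92
MCODE	High	Lit-4	7	7	8.99	0.13	0.89	0.79	0.71
MCODE	High	Ortho-4	12	9	9.37	0.31	0.51	0.59	0.54
MCODE	High	Ortho-5	9	7	12.92	0.77	0.65	0.78	0.71
MCODE	Low	Lit-11	9	8	8.34	0.24	0.4	0.59	0.69
MCODE	Low	Lit-13	22	20	8.81	0.32	0.33	0.5	0.63
MCODE	Low	Ortho-2	6	5	8.08	0.29	0.41	0.78	0.73
MCODE	Low	Ortho-10	11	9	8.38	0.38	0.39	0.52	0.67
CPM	Residual	Int-1	1496	1348	8.73	0.13	NA	NA	NA
CPM	Residual	Int-5	7	4	10.71	0.57	0.31	0.35	0.42
CPM	Residual	Int-6	8	5	8.39	0.39	0.34	0.32	0.54
CPM	Residual	Int-8	8	8	9.5	0.44	0.5	0.46	0.62
CPM	Residual	Int-9	8	6	8.68	0.49	0.27	0.46	0.81
CPM	Residual	Int-10	12	10	8.64	0.41	0.39	0.49	0.61
CPM	Residual	Int-11	9	9	9.08	0.41	0.42	0.26	0.64
CPM	Residual	Int-12	11	10	8.84	0.26	0.35	0.36	0.5
CPM	Residual	Int-14	14	9	8.76	0.4	0.37	0.2	0.67
CPM	Residual	Int-15	15	9	8.42	0.46	0.55	0.23	0.8
CPM	Residual	Int-16	14	8	8.42	0.46	0.43	0.21	0.76
CPM	Residual	Int-17	28	13	12.06	0.6	0.46	0.56	0.49
CPM	Residual	Int-19	21	9	10.03	0.28	0.4	0.48	0.47
CPM	Residual	Int-20	18	6	9.07	0.36	0.47	0.34	0.59
CPM	Residual	Int-21	22	10	9.5	0.12	0.39	0.48	0.47
CPM	Residual	Lit-1	1141	1081	8.6	0.12	NA	NA	NA
CPM	Residual	Lit-3	6	6	9.37	0.15	0.69	0.15	0.37
CPM	Residual	Lit-6	6	6	8.21	0.63	0.55	0.44	0.56
CPM	Residual	Lit-7	8	5	8.39	0.39	0.34	0.32	0.54
CPM	Residual	Lit-8	7	5	8.14	0.18	0.76	0.19	0.42
CPM	Residual	Lit-10	10	10	9.32	0.46	0.35	0.15	0.77
CPM	Residual	Lit-12	9	9	8.64	0.11	0.22	0.27	0.38
CPM	Residual	Lit-13	11	10	8.84	0.26	0.35	0.36	0.5
CPM	Residual	Ortho-1	7	2	8.6	0.5	0.41	0.19	0.57
CPM	Residual	Ortho-2	4	3	8.34	0.37	0.62	0.22	0.55
CPM	Residual	Ortho-3	4	3	8.58	-0.18	0.54	0.35	0.7
CPM	Residual	Ortho-4	4	4	8.65	0.69	0.44	0.45	0.48
CPM	Residual	Ortho-5	14	10	8.86	0.1	0.34	0.24	0.39
CPM	Residual	Ortho-6	7	4	10.71	0.57	0.31	0.35	0.42
CPM	Residual	Ortho-9	8	8	9.5	0.44	0.5	0.46	0.62
CPM	Residual	Ortho-10	8	6	8.68	0.49	0.27	0.46	0.81
CPM	Residual	Ortho-11	12	10	8.64	0.41	0.39	0.49	0.61
CPM	Residual	Ortho-13	58	29	10.81	0.42	0.38	0.47	0.47
CPM	Residual	Ortho-14	24	7	9.21	0.39	0.45	0.43	0.61
CPM	Residual	Ortho-15	14	9	8.76	0.4	0.37	0.2	0.67
CPM	Residual	Ortho-16	39	22	10.67	0.35	0.43	0.49	0.49
CPM	Residual	Ortho-17	15	9	8.42	0.46	0.55	0.23	0.8
CPM	Residual	Ortho-19	21	9	10.03	0.28	0.4	0.48	0.47
CPM	Residual	Ortho-20	18	6	9.07	0.36	0.47	0.34	0.59
CPM	Residual	Ortho-21	22	10	9.5	0.12	0.39	0.48	0.47
CPM	Residual	HTP-1	5	5	12.73	0.21	0.55	0.2	0.56
CPM	Residual	HTP-2	3	3	7.79	0.06	0.78	0.24	0.39
CPM	Residual	HTP-3	3	2	7.33	0.07	0.46	0.1	1
CPM	Residual	HTP-4	145	108	8.33	0.06	NA	NA	NA
CPM	Residual	HTP-5	3	2	7.97	0.05	0.44	0.05	0.29
CPM	Residual	HTP-6	163	120	8.99	0.15	NA	NA	NA
CPM	Residual	HTP-7	44	36	8.96	0.16	0.34	0.17	0.44
CPM	Residual	HTP-8	7	5	8.38	-0.06	0.31	0.12	0.31
CPM	Residual	HTP-9	5	5	9.16	0.03	0.78	0.36	0.66
MCODE	Residual	Int-1	14	13	7.37	0.1	0.49	0.44	0.5
MCODE	Residual	Int-2	9	7	7.83	-0.02	0.27	0.24	0.52
MCODE	Residual	Int-3	13	9	8.66	0.33	0.47	0.41	0.66
MCODE	Residual	Int-4	13	12	8.29	0.06	0.4	0.44	0.58
MCODE	Residual	Int-6	75	68	8.46	0.2	0.24	0.18	0.4
MCODE	Residual	Int-7	58	43	8.3	0.19	0.26	0.16	0.38
MCODE	Residual	Int-8	47	39	9.1	0.23	0.25	0.17	0.44
MCODE	Residual	Int-9	74	70	9.44	0.28	0.27	0.24	0.43
MCODE	Residual	Int-10	10	6	10.28	0.77	0.65	0.43	0.77
MCODE	Residual	Int-11	29	27	9.12	0.4	0.36	0.33	0.63
MCODE	Residual	Int-12	32	28	8.72	0.35	0.31	0.41	0.61
MCODE	Residual	Int-13	79	46	9.99	0.49	0.36	0.31	0.48
MCODE	Residual	Int-14	29	12	9.77	0.23	0.37	0.44	0.43
MCODE	Residual	Lit-1	5	5	7.87	0.02	0.53	0.06	0.46
MCODE	Residual	Lit-2	7	7	8.47	-0.01	0.44	0.32	0.74
MCODE	Residual	Lit-3	145	139	8.42	0.06	0.25	0.15	0.35
MCODE	Residual	Lit-5	5	2	8.69	0.16	0.3	0.16	0.61
MCODE	Residual	Lit-6	144	140	8.69	0.1	0.26	0.19	0.41
MCODE	Residual	Lit-7	21	21	7.98	0.05	0.33	0.19	0.39
MCODE	Residual	Lit-8	98	96	8.72	0.16	0.24	0.24	0.41
MCODE	Residual	Lit-9	15	15	8.67	0.15	0.26	0.2	0.45
MCODE	Residual	Lit-10	128	122	8.62	0.21	0.28	0.16	0.42
MCODE	Residual	Lit-12	40	39	8.79	0.23	0.29	0.28	0.51
MCODE	Residual	Ortho-1	6	3	11.12	0.67	0.32	0.37	0.39
MCODE	Residual	Ortho-3	12	8	8.65	0.32	0.45	0.37	0.66
MCODE	Residual	Ortho-6	13	6	8.38	0.24	0.28	0.2	0.53
MCODE	Residual	Ortho-7	10	10	9.16	0.12	0.44	0.21	0.68
MCODE	Residual	Ortho-8	23	20	10.08	0.51	0.35	0.33	0.56
MCODE	Residual	Ortho-9	10	6	10.28	0.77	0.65	0.43	0.77
MCODE	Residual	Ortho-11	44	31	10.58	0.53	0.35	0.43	0.48
MCODE	Residual	Ortho-12	35	15	8.81	0.45	0.44	0.28	0.64
MCODE	Residual	Ortho-13	35	15	8.81	0.45	0.44	0.28	0.64
MCODE	Residual	Ortho-14	29	12	9.77	0.23	0.37	0.44	0.43
MCODE	Residual	HTP-1	67	56	8.74	0.12	0.3	0.16	0.41
MCODE	Residual	HTP-2	17	15	9.23	0.17	0.45	0.16	0.44
MCODE	Residual	HTP-3	20	18	9.06	0.08	0.45	0.28	0.5
MCODE	Residual	HTP-4	17	15	8.83	0.14	0.38	0.16	0.37
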