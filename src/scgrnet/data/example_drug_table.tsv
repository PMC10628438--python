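# synthetic drug-target snapshot v1 (fixture)
drug_id	drug_name	gene_symbol	action	source
D001	examplin-1	GENE01		synthetic
D001	examplin-1	GENE04		synthetic
D002	examplin-2	GENE02	inhibitor	synthetic
D003	examplin-3	GENE03		synthetic
D004	examplin-4	GENE04	inhibitor	synthetic
D004	examplin-4	GENE07	inhibitor	synthetic
D005	examplin-5	GENE05		synthetic
D006	examplin-6	GENE06	inhibitor	synthetic
D007	examplin-7	GENE02		synthetic
D007	examplin-7	GENE07		synthetic
D008	examplin-8	GENE08	inhibitor	synthetic
D009	examplin-9	GENE01		synthetic
D010	examplin-10	GENE02	inhibitor	synthetic
D010	examplin-10	GENE05	inhibitor	synthetic
D011	examplin-11	GENE03		synthetic
D012	examplin-12	GENE04	inhibitor	synthetic
D013	examplin-13	GENE05		synthetic
D013	examplin-13	GENE08		synthetic
D014	examplin-14	GENE06	inhibitor	synthetic
D015	examplin-15	GENE07		synthetic
D016	examplin-16	GENE03	inhibitor	synthetic
D016	examplin-16	GENE08	inhibitor	synthetic
D017	examplin-17	GENE01		synthetic
D018	examplin-18	GENE02	inhibitor	synthetic
D019	examplin-19	GENE03		synthetic
D019	examplin-19	GENE06		synthetic
D020	examplin-20	GENE04	inhibitor	synthetic
D900	offex-0	OFF00		synthetic
D901	offex-1	OFF01		synthetic
D902	offex-2	OFF02		synthetic
D903	offex-3	OFF03		synthetic
D904	offex-4	OFF04		synthetic
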