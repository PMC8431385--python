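pathway_id	term_id	intersection	pathway_size	fraction	labeled
P000	GO:0006915	13	26	0.5	True
P000	GO:0006954	0	26	0.0	False
P000	GO:0006974	0	26	0.0	False
P000	GO:0006979	0	26	0.0	False
P001	GO:0006915	21	35	0.6	True
P001	GO:0006954	0	35	0.0	False
P001	GO:0006974	0	35	0.0	False
P001	GO:0006979	0	35	0.0	False
P002	GO:0006915	14	20	0.7	True
P002	GO:0006954	0	20	0.0	False
P002	GO:0006974	0	20	0.0	False
P002	GO:0006979	0	20	0.0	False
P003	GO:0006915	8	10	0.8	True
P003	GO:0006954	0	10	0.0	False
P003	GO:0006974	0	10	0.0	False
P003	GO:0006979	0	10	0.0	False
P004	GO:0006915	0	22	0.0	False
P004	GO:0006954	11	22	0.5	True
P004	GO:0006974	0	22	0.0	False
P004	GO:0006979	0	22	0.0	False
P005	GO:0006915	0	15	0.0	False
P005	GO:0006954	6	15	0.4	False
P005	GO:0006974	0	15	0.0	False
P005	GO:0006979	0	15	0.0	False
P006	GO:0006915	0	20	0.0	False
P006	GO:0006954	0	20	0.0	False
P006	GO:0006974	10	20	0.5	True
P006	GO:0006979	0	20	0.0	False
P007	GO:0006915	0	30	0.0	False
P007	GO:0006954	0	30	0.0	False
P007	GO:0006974	24	30	0.8	True
P007	GO:0006979	0	30	0.0	False
P008	GO:0006915	0	28	0.0	False
P008	GO:0006954	0	28	0.0	False
P008	GO:0006974	0	28	0.0	False
P008	GO:0006979	14	28	0.5	True
P009	GO:0006915	15	30	0.5	True
P009	GO:0006954	15	30	0.5	True
P009	GO:0006974	0	30	0.0	False
P009	GO:0006979	0	30	0.0	False
P010	GO:0006915	14	35	0.4	False
P010	GO:0006954	0	35	0.0	False
P010	GO:0006974	0	35	0.0	False
P010	GO:0006979	0	35	0.0	False
P011	GO:0006915	0	25	0.0	False
P011	GO:0006954	0	25	0.0	False
P011	GO:0006974	0	25	0.0	False
P011	GO:0006979	15	25	0.6	True
P012	GO:0006915	0	33	0.0	False
P012	GO:0006954	0	33	0.0	False
P012	GO:0006974	0	33	0.0	False
P012	GO:0006979	0	33	0.0	False
P013	GO:0006915	0	37	0.0	False
P013	GO:0006954	0	37	0.0	False
P013	GO:0006974	0	37	0.0	False
P013	GO:0006979	0	37	0.0	False
P014	GO:0006915	0	23	0.0	False
P014	GO:0006954	0	23	0.0	False
P014	GO:0006974	0	23	0.0	False
P014	GO:0006979	0	23	0.0	False
P015	GO:0006915	0	21	0.0	False
P015	GO:0006954	0	21	0.0	False
P015	GO:0006974	0	21	0.0	False
P015	GO:0006979	0	21	0.0	False
P016	GO:0006915	0	13	0.0	False
P016	GO:0006954	0	13	0.0	False
P016	GO:0006974	0	13	0.0	False
P016	GO:0006979	0	13	0.0	False
P017	GO:0006915	0	37	0.0	False
P017	GO:0006954	0	37	0.0	False
P017	GO:0006974	0	37	0.0	False
P017	GO:0006979	0	37	0.0	False
P018	GO:0006915	0	18	0.0	False
P018	GO:0006954	0	18	0.0	False
P018	GO:0006974	0	18	0.0	False
P018	GO:0006979	0	18	0.0	False
P019	GO:0006915	0	23	0.0	False
P019	GO:0006954	0	23	0.0	False
P019	GO:0006974	0	23	0.0	False
P019	GO:0006979	0	23	0.0	False
P020	GO:0006915	0	32	0.0	False
P020	GO:0006954	0	32	0.0	False
P020	GO:0006974	0	32	0.0	False
P020	GO:0006979	0	32	0.0	False
P021	GO:0006915	0	18	0.0	False
P021	GO:0006954	0	18	0.0	False
P021	GO:0006974	0	18	0.0	False
P021	GO:0006979	0	18	0.0	False
P022	GO:0006915	0	23	0.0	False
P022	GO:0006954	0	23	0.0	False
P022	GO:0006974	0	23	0.0	False
P022	GO:0006979	0	23	0.0	False
P023	GO:0006915	0	22	0.0	False
P023	GO:0006954	0	22	0.0	False
P023	GO:0006974	0	22	0.0	False
P023	GO:0006979	0	22	0.0	False
P024	GO:0006915	0	28	0.0	False
P024	GO:0006954	0	28	0.0	False
P024	GO:0006974	0	28	0.0	False
P024	GO:0006979	0	28	0.0	False
P025	GO:0006915	0	20	0.0	False
P025	GO:0006954	0	20	0.0	False
P025	GO:0006974	0	20	0.0	False
P025	GO:0006979	0	20	0.0	False
P026	GO:0006915	0	24	0.0	False
P026	GO:0006954	0	24	0.0	False
P026	GO:0006974	0	24	0.0	False
P026	GO:0006979	0	24	0.0	False
P027	GO:0006915	0	34	0.0	False
P027	GO:0006954	0	34	0.0	False
P027	GO:0006974	0	34	0.0	False
P027	GO:0006979	0	34	0.0	False
P028	GO:0006915	0	10	0.0	False
P028	GO:0006954	0	10	0.0	False
P028	GO:0006974	0	10	0.0	False
P028	GO:0006979	0	10	0.0	False
P029	GO:0006915	0	28	0.0	False
P029	GO:0006954	0	28	0.0	False
P029	GO:0006974	0	28	0.0	False
P029	GO:0006979	0	28	0.0	False
P030	GO:0006915	0	35	0.0	False
P030	GO:0006954	0	35	0.0	False
P030	GO:0006974	0	35	0.0	False
P030	GO:0006979	0	35	0.0	False
P031	GO:0006915	0	24	0.0	False
P031	GO:0006954	0	24	0.0	False
P031	GO:0006974	0	24	0.0	False
P031	GO:0006979	0	24	0.0	False
P032	GO:0006915	0	34	0.0	False
P032	GO:0006954	0	34	0.0	False
P032	GO:0006974	0	34	0.0	False
P032	GO:0006979	0	34	0.0	False
P033	GO:0006915	0	27	0.0	False
P033	GO:0006954	0	27	0.0	False
P033	GO:0006974	0	27	0.0	False
P033	GO:0006979	0	27	0.0	False
P034	GO:0006915	0	17	0.0	False
P034	GO:0006954	0	17	0.0	False
P034	GO:0006974	0	17	0.0	False
P034	GO:0006979	0	17	0.0	False
P035	GO:0006915	0	27	0.0	False
P035	GO:0006954	0	27	0.0	False
P035	GO:0006974	0	27	0.0	False
P035	GO:0006979	0	27	0.0	False
P036	GO:0006915	0	40	0.0	False
P036	GO:0006954	0	40	0.0	False
P036	GO:0006974	0	40	0.0	False
P036	GO:0006979	0	40	0.0	False
P037	GO:0006915	0	34	0.0	False
P037	GO:0006954	0	34	0.0	False
P037	GO:0006974	0	34	0.0	False
P037	GO:0006979	0	34	0.0	False
P038	GO:0006915	0	33	0.0	False
P038	GO:0006954	0	33	0.0	False
P038	GO:0006974	0	33	0.0	False
P038	GO:0006979	0	33	0.0	False
P039	GO:0006915	0	25	0.0	False
P039	GO:0006954	0	25	0.0	False
P039	GO:0006974	0	25	0.0	False
P039	GO:0006979	0	25	0.0	False
P040	GO:0006915	0	19	0.0	False
P040	GO:0006954	0	19	0.0	False
P040	GO:0006974	0	19	0.0	False
P040	GO:0006979	0	19	0.0	False
P041	GO:0006915	0	37	0.0	False
P041	GO:0006954	0	37	0.0	False
P041	GO:0006974	0	37	0.0	False
P041	GO:0006979	0	37	0.0	False
P042	GO:0006915	0	14	0.0	False
P042	GO:0006954	0	14	0.0	False
P042	GO:0006974	0	14	0.0	False
P042	GO:0006979	0	14	0.0	False
P043	GO:0006915	0	34	0.0	False
P043	GO:0006954	0	34	0.0	False
P043	GO:0006974	0	34	0.0	False
P043	GO:0006979	0	34	0.0	False
P044	GO:0006915	0	16	0.0	False
P044	GO:0006954	0	16	0.0	False
P044	GO:0006974	0	16	0.0	False
P044	GO:0006979	0	16	0.0	False
P045	GO:0006915	0	29	0.0	False
P045	GO:0006954	0	29	0.0	False
P045	GO:0006974	0	29	0.0	False
P045	GO:0006979	0	29	0.0	False
P046	GO:0006915	0	24	0.0	False
P046	GO:0006954	0	24	0.0	False
P046	GO:0006974	0	24	0.0	False
P046	GO:0006979	0	24	0.0	False
P047	GO:0006915	0	28	0.0	False
P047	GO:0006954	0	28	0.0	False
P047	GO:0006974	0	28	0.0	False
P047	GO:0006979	0	28	0.0	False
P048	GO:0006915	0	18	0.0	False
P048	GO:0006954	0	18	0.0	False
P048	GO:0006974	0	18	0.0	False
P048	GO:0006979	0	18	0.0	False
P049	GO:0006915	0	22	0.0	False
P049	GO:0006954	0	22	0.0	False
P049	GO:0006974	0	22	0.0	False
P049	GO:0006979	0	22	0.0	False
P050	GO:0006915	0	39	0.0	False
P050	GO:0006954	0	39	0.0	False
P050	GO:0006974	0	39	0.0	False
P050	GO:0006979	0	39	0.0	False
P051	GO:0006915	0	39	0.0	False
P051	GO:0006954	0	39	0.0	False
P051	GO:0006974	0	39	0.0	False
P051	GO:0006979	0	39	0.0	False
P052	GO:0006915	0	13	0.0	False
P052	GO:0006954	0	13	0.0	False
P052	GO:0006974	0	13	0.0	False
P052	GO:0006979	0	13	0.0	False
P053	GO:0006915	0	37	0.0	False
P053	GO:0006954	0	37	0.0	False
P053	GO:0006974	0	37	0.0	False
P053	GO:0006979	0	37	0.0	False
P054	GO:0006915	0	27	0.0	False
P054	GO:0006954	0	27	0.0	False
P054	GO:0006974	0	27	0.0	False
P054	GO:0006979	0	27	0.0	False
P055	GO:0006915	0	16	0.0	False
P055	GO:0006954	0	16	0.0	False
P055	GO:0006974	0	16	0.0	False
P055	GO:0006979	0	16	0.0	False
P056	GO:0006915	0	22	0.0	False
P056	GO:0006954	0	22	0.0	False
P056	GO:0006974	0	22	0.0	False
P056	GO:0006979	0	22	0.0	False
P057	GO:0006915	0	26	0.0	False
P057	GO:0006954	0	26	0.0	False
P057	GO:0006974	0	26	0.0	False
P057	GO:0006979	0	26	0.0	False
P058	GO:0006915	0	40	0.0	False
P058	GO:0006954	0	40	0.0	False
P058	GO:0006974	0	40	0.0	False
P058	GO:0006979	0	40	0.0	False
P059	GO:0006915	0	13	0.0	False
P059	GO:0006954	0	13	0.0	False
P059	GO:0006974	0	13	0.0	False
P059	GO:0006979	0	13	0.0	False
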