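feature	category	mean_pos	std_pos	mean_neg	std_neg	p_value
Pscore_AA_Q__P_75_	PSSM score based	0.696	0.095	0.626	0.124	<0.001
AvePscore_AA_Y__Res_K_	PSSM score based	0.160	0.078	0.207	0.093	<0.001
AveRSA_Res_G_	Average RSA based	0.310	0.076	0.271	0.061	<0.001
AvePscore_AA_P_	PSSM score based	0.232	0.049	0.255	0.058	<0.001
DIC_Res_KS_	AA composition based	0.005	0.006	0.004	0.005	0.019
AvePscore_AA_R__Res_G_	PSSM score based	0.227	0.124	0.224	0.096	0.765
AutoCC_AA_N_ _Lag_7_	PSSM score based	-0.014	0.106	0.010	0.095	0.003
AvePscore_AA_G__Res_R_	PSSM score based	0.170	0.094	0.207	0.103	<0.001
AvePscore_AA_L_	PSSM score based	0.323	0.057	0.329	0.048	0.117
AvePscore_AA_K__Res_G_	PSSM score based	0.276	0.122	0.266	0.100	0.272
AvePscore_AA_Q_	PSSM score based	0.422	0.040	0.396	0.051	<0.001
AvePscore_AA_R__Res_M_	PSSM score based	0.250	0.164	0.229	0.124	0.080
AAC_Res_R__Ex_0.2_	AA composition based	0.092	0.043	0.080	0.037	<0.001
AvePscore_AA_T_	PSSM score based	0.377	0.037	0.387	0.040	0.001
AAC_Res_D__Bu_0.3_	AA composition based	0.018	0.019	0.024	0.016	<0.001
AAC_Res_V__Ex_0.1_	AA composition based	0.039	0.022	0.045	0.019	<0.001
AutoCC_AA_R_ _Lag_7_	PSSM score based	0.008	0.091	0.031	0.100	0.004
AAC_Res_N_	AA composition based	0.038	0.021	0.043	0.022	0.003
AvePscore_AA_C__Res_N_	PSSM score based	0.141	0.140	0.136	0.096	0.644
AutoCC_AA_I_ _Lag_7_	PSSM score based	-0.015	0.092	0.009	0.097	0.002
AAC_Res_D__Bu_0.2_	AA composition based	0.012	0.018	0.016	0.015	0.004
AvePscore_AA_G__Res_K_	PSSM score based	0.197	0.090	0.232	0.107	<0.001
AvePscore_AA_R__Res_E_	PSSM score based	0.493	0.100	0.478	0.085	0.044
AutoCC_AA_I_ _Lag_8_	PSSM score based	-0.010	0.105	-0.005	0.076	0.511
AAC_Res_A__Ex_0.1_	AA composition based	0.062	0.035	0.068	0.037	0.04
AAC_Res_T__Ex_0.3_	AA composition based	0.044	0.028	0.055	0.033	<0.001
AutoCC_AA_P_ _Lag_7_	PSSM score based	-0.011	0.110	0.021	0.096	<0.001
AutoCC_AA_E_ _Lag_4_	PSSM score based	0.106	0.120	0.100	0.125	0.524
AAC_Res_E__Ex_0.1_	AA composition based	0.093	0.032	0.088	0.035	0.049
AutoCC_AA_I_ _Lag_3_	PSSM score based	0.029	0.092	0.007	0.085	0.003
AutoCC_AA_K_ _Lag_7_	PSSM score based	0.021	0.101	0.041	0.105	0.018
AvePscore_AA_R_ _Res_R_	PSSM score based	0.930	0.086	0.892	0.121	<0.001
AutoCC_AA_R__Lag_9_	PSSM score based	-0.021	0.110	-0.007	0.079	0.084
AAC_Res_L__Bu_0.5_	AA composition based	0.111	0.038	0.102	0.031	0.003
AvePscore_AA_R__Res_W_	PSSM score based	0.124	0.200	0.167	0.202	0.008
Pscore_AA_R_ _P_75_	PSSM score based	0.661	0.154	0.584	0.152	<0.001
AAC_Res_T__Ex_0.4_	AA composition based	0.035	0.033	0.044	0.036	0.002
AvePscore_AA_I__Res_D_	PSSM score based	0.089	0.065	0.108	0.059	<0.001
AvePscore_AA_N__Res_R_	PSSM score based	0.402	0.106	0.417	0.108	0.105
AutoCC_AA_V_ _Lag_8_	PSSM score based	-0.015	0.099	-0.009	0.077	0.381
AvePscore_AA_H__Res_W_	PSSM score based	0.145	0.202	0.214	0.211	<0.001
AvePscore_AA_R_	PSSM score based	0.387	0.055	0.357	0.055	<0.001
AvePscore_AA_W__Res_T_	PSSM score based	0.094	0.083	0.148	0.110	<0.001
AAC_Res_N__Bu_0.2_	AA composition based	0.011	0.016	0.015	0.015	0.001
AutoCC_AA_I_ _Lag_4_	PSSM score based	0.014	0.106	-0.010	0.099	0.004
AvePscore_AA_E_	PSSM score based	0.407	0.043	0.391	0.055	<0.001
DIP_Res_DL_	AA composition based	0.005	0.006	0.005	0.005	0.687
AvePscore_AA_N__Res_I_	PSSM score based	0.104	0.085	0.129	0.080	<0.001
AutoCC_AA_C__Lag_7_	PSSM score based	-0.002	0.103	0.020	0.082	0.003
AutoCC_AA_L_ _Lag_7_	PSSM score based	-0.005	0.101	0.016	0.103	0.012
AvePscore_AA_I__Res_A_	PSSM score based	0.285	0.100	0.287	0.098	0.745
AAC_Res_A__Bu_0.2_	AA composition based	0.096	0.056	0.102	0.050	0.158
AAC_Res_E_	AA composition based	0.074	0.025	0.069	0.027	0.009
AutoCC_AA_T__Lag_2_	PSSM score based	0.011	0.101	0.050	0.090	<0.001
AAC_Res_T__Ex_0.2_	AA composition based	0.052	0.027	0.061	0.029	<0.001
AAC_Res_C__SS_C_	AA composition based	0.011	0.023	0.016	0.024	0.019
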