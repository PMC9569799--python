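name	value	unit	source
m_gy	0.14	Gy	base-model
dsb_per_gy	40.0	DSB/Gy	standard-yield
atm_total	200.0	copies	calibrated
k_atm_act	1e-5	1/s	calibrated
k_atm_deact	1.2e-3	1/s	calibrated
k_atm_wip1	2.0	1/(copies*s)	calibrated
s_p53	0.3	copies/s	calibrated
d_p53	5e-5	1/s	calibrated
d_p53_mdm2	8e-5	1/(copies*s)	calibrated
k_p53_phos	2e-5	1/(copies*s)	calibrated
k_arr_dephos	4e-5	1/(copies*s)	calibrated
d_arr_mdm2	5e-6	1/(copies*s)	calibrated
k_killer_phos	2e-6	1/(copies*s)	calibrated
k_killer_dephos	5e-8	1/(copies*s)	calibrated
d_kil_mdm2	5e-8	1/(copies*s)	calibrated
s_mdm2_mrna	0.02	copies/s	calibrated
s_mdm2_mrna0	0.002	copies/s	calibrated
d_mdm2_mrna	2e-4	1/s	calibrated
k_mdm2_tln	2e-3	1/s	calibrated
d_mdm2	2.5e-4	1/s	calibrated
d_mdm2_atm	2e-6	1/(copies*s)	calibrated
K_mdm2	150.0	copies	calibrated
s_wip1_mrna	0.0221	copies/s	calibrated
s_wip1_mrna0	5e-5	copies/s	calibrated
d_wip1_mrna	2.6e-4	1/s	calibrated
k_wip1_tln	5.2e-4	1/s	calibrated
d_wip1	1.3e-4	1/s	calibrated
K_wip1	60.0	copies	calibrated
s_p21_mrna	0.06	copies/s	calibrated
s_p21_mrna0	0.001	copies/s	calibrated
d_p21_mrna	3e-4	1/s	calibrated
k_p21_tln	6e-4	1/s	calibrated
d_p21	6e-5	1/s	calibrated
K_p21	70.0	copies	calibrated
s_cyce	0.12	copies/s	calibrated
d_cyce	4e-4	1/s	calibrated
K_cyce	60.0	copies	calibrated
s_bax_mrna	0.01	copies/s	calibrated
s_bax_mrna0	5e-4	copies/s	calibrated
d_bax_mrna	2e-4	1/s	calibrated
k_bax_tln	1e-3	1/s	calibrated
d_bax	1e-4	1/s	calibrated
d_bax_akt	2e-6	1/(copies*s)	calibrated
K_bax	105.0	copies	calibrated
s_akt	0.06	copies/s	calibrated
d_akt	2e-4	1/s	calibrated
K_akt	105.0	copies	calibrated
s_gadd45	0.03	copies/s	calibrated
s_gadd450	0.001	copies/s	calibrated
d_gadd45	2e-4	1/s	calibrated
K_gadd45	120.0	copies	calibrated
s_p38	0.06	copies/s	calibrated
s_p380	0.002	copies/s	calibrated
d_p38	2e-4	1/s	calibrated
K_p38	75.0	copies	calibrated
s_tgfb	0.03	copies/s	calibrated
d_tgfb	2e-5	1/s	calibrated
K_tgfb	150.0	copies	calibrated
k_atm_auto	3e-5	1/s	calibrated
K_atm_wip1	60.0	copies	calibrated
d_killer	5e-6	1/s	calibrated
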