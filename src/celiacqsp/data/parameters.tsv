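name	value	unit	source	ci_lo	ci_hi
inflow_gluten	10.0	au/d	literature		
inflow_gfd	0.02	au/d	calculated		
kdeg_glut_lum	10.0	1/d	literature		
k_transport_zon	0.7059725702128683	1/(au*d)	fitted	0.3529862851064341	1.4119451404257366
k_transport_iec	0.4283307819628882	1/d	fitted	0.21416539098144408	0.8566615639257764
kdeg_glut_lam	1.0	1/d	literature		
kdeg_dglut	1.0	1/d	literature		
k_deam	2.542567580320929	1/(au*d)	fitted	1.2712837901604646	5.085135160641858
tg2_level	1.0	au	literature		
k_iec_maturation	0.2	au/d	calculated		
ki_ab_maturation	0.0514339644080054	au	fitted	0.02571698220400269	0.10286792881601078
kd_iec	0.2	1/d	literature		
kd_aiec	37.02797788410547	1/d	fitted	18.51398894205273	74.05595576821095
k_iec_activation	0.0657794119957656	1/d	fitted	0.035963722604658785	0.12978977828763572
kact_iec_half	0.0001	au	literature		
h_iec_activation	4.0	-	assumed		
k_iec_death_aiel	0.0124093776075171	1/(au*d)	fitted	0.006204688803758553	0.024818755215034204
k_iec_death_if21	2.0825299648935656	1/(au*d)	fitted	1.0412649824467828	4.165059929787131
k_iec_death_ab	1.8062900359202017e-05	1/(au*d)	fitted	9.031450179601007e-06	3.6125800718404034e-05
iec_healthy	1.0	au	calculated		
k_zon_syn	213.58401880437276	1/d	fitted	106.79200940218635	427.1680376087455
kdeg_zon	2.0	1/d	literature		
k_il15_aiec	724.4508272939426	1/d	fitted	362.2254136469712	1448.9016545878853
k_il15_aapc	5.360000000000001	1/d	fitted	3.6117593019913063	10.72
kdeg_il15	2.0	1/d	literature		
k_iel_source	1.0	au/d	literature		
kd_iel	0.1	1/d	literature		
k_iel_activation	0.0442957127138436	1/d	fitted	0.022147856356921795	0.0885914254276872
k_il15_iel_half	1.5	au	fitted	0.75	2.684784423482102
h_iel_activation	2.0	-	assumed		
kd_aiel	5.4	1/d	fitted	2.7	10.799999999999999
ki_il15_apoptosis	0.0176742607973865	au	fitted	0.008837130398693252	0.035348521594773
k_apc_diff_basal	0.14062	au/d	fitted	0.1004616969475402	0.28124000000000005
k_apc_diff_il15	1.7046622849770556	au/d	fitted	0.8523311424885278	3.409324569954111
k_il15_apc_half	59.00261427849932	au	fitted	29.501307139249658	118.0052285569986
kd_apc	0.5	1/d	literature		
kd_aapc	0.7	1/d	fitted	0.35	0.9546759872932561
k_apc_activation	4.453997818630531	1/d	fitted	2.2269989093152653	8.907995637261061
ec50_deam	0.1199999999999999	au	fitted	0.059999999999999935	0.23999999999999982
ec50_nat	0.5999999999999995	au	calculated		
k_t_source	1.0	au/d	literature		
kd_t	0.2	1/d	literature		
k_t_activation	0.0008865842346132	1/(au*d)	fitted	0.0004432921173066	0.0017731684692264005
a_if21_boost	0.002222222222222	-	fitted	0.001111111111111	0.004444444444444001
k_if21_boost_half	71.99999999999994	au	fitted	35.999999999999964	143.9999999999999
k_t_transition	0.3	1/d	fitted	0.14999999999999997	0.6
kd_at	0.1071519305237606	1/d	fitted	0.05357596526188029	0.21430386104752122
k_if21_at	0.106	1/d	fitted	0.052999999999999985	0.212
k_if21_aiel	1.94	1/d	fitted	0.97	3.8800000000000003
kdeg_ifng	2.2	1/d	literature		
kdeg_il21	1.8	1/d	literature		
k_ab_syn	1.5065334179110397	1/d	fitted	0.7532667089555198	3.0130668358220793
k_ab_pep_half	2.002027341652767	au	fitted	1.0010136708263835	4.004054683305533
kdeg_ab	0.04	1/d	literature		
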