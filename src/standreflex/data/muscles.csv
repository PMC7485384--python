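name,f_max,l_opt,l_slack,pennation,v_max,see_ref_strain,tau_act,tau_deact,fl_width,fv_curvature,fv_ecc,damping,ce_ref,arm_hip,arm_knee,arm_ankle
iliopsoas,2500.0,0.11,0.1,0.5,12.0,0.04,0.01,0.04,0.56,5.0,1.5,0.1,0.8,0.08,0.0,0.0
gluteals,3000.0,0.11,0.13,0.5,12.0,0.04,0.01,0.04,0.56,5.0,1.5,0.1,0.8,-0.08,0.0,0.0
rectus_femoris,1200.0,0.081,0.35,0.5,12.0,0.04,0.01,0.04,0.56,5.0,1.5,0.1,0.8,0.05,-0.05,0.0
biceps_femoris_lh,3000.0,0.1,0.31,0.7,12.0,0.04,0.01,0.04,0.56,5.0,1.5,0.1,0.8,-0.08,0.05,0.0
biceps_femoris_sh,1200.0,0.12,0.1,0.7,12.0,0.04,0.01,0.04,0.56,5.0,1.5,0.1,0.8,0.0,0.04,0.0
vastus,6000.0,0.08,0.23,0.6,12.0,0.04,0.01,0.04,0.56,5.0,1.5,0.1,0.8,0.0,-0.06,0.0
gastrocnemius,1500.0,0.05,0.4,0.7,12.0,0.04,0.01,0.04,0.56,5.0,1.5,0.1,0.8,0.0,0.05,-0.05
soleus,4000.0,0.04,0.26,0.5,6.0,0.04,0.01,0.04,0.56,5.0,1.5,0.1,0.8,0.0,0.0,-0.05
tibialis_anterior,4000.0,0.06,0.24,0.7,12.0,0.04,0.01,0.04,0.56,5.0,1.5,0.1,0.8,0.0,0.0,0.04
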