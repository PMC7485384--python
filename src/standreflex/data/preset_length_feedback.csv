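name,u0,g_ffb,g_lfb,l_off,value
iliopsoas,0.20,0.0,0.23,0.52,
gluteals,0.034,0.0,-0.45,0.73,
rectus_femoris,0.20,0.0,0.12,0.67,
biceps_femoris_lh,0.32,0.0,-0.28,0.86,
biceps_femoris_sh,0.16,0.0,0.22,0.26,
vastus,0.24,0.0,-0.042,0.58,
gastrocnemius,0.067,0.0,-0.63,0.86,
soleus,0.33,0.0,1.15,0.50,
tibialis_anterior,0.0076,0.0,-0.38,0.70,
x_heel,,,,,0.0660
x_toe,,,,,0.0266
z_heel,,,,,0.27
z_toe,,,,,0.67
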