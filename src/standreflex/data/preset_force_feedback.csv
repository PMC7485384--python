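name,u0,g_ffb,g_lfb,l_off,value
iliopsoas,0.21,0.31,0.0,1.1,
gluteals,0.14,1.38,0.0,1.1,
rectus_femoris,0.17,0.50,0.0,1.1,
biceps_femoris_lh,0.30,0.11,0.0,1.1,
biceps_femoris_sh,0.12,0.48,0.0,1.1,
vastus,0.30,0.031,0.0,1.1,
gastrocnemius,0.17,0.31,0.0,1.1,
soleus,0.21,1.36,0.0,1.1,
tibialis_anterior,0.045,-1.45,0.0,1.1,
x_heel,,,,,0.0599
x_toe,,,,,0.0182
z_heel,,,,,0.32
z_toe,,,,,0.53
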