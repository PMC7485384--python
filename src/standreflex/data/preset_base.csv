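name,u0,g_ffb,g_lfb,l_off,value
iliopsoas,0.25,1.01,0.72,1.02,
gluteals,0.14,0.89,0.029,0.94,
rectus_femoris,0.093,0.24,-0.54,0.64,
biceps_femoris_lh,0.26,0.53,-1.07,0.67,
biceps_femoris_sh,0.11,0.25,0.66,0.76,
vastus,0.26,-0.23,0.21,0.39,
gastrocnemius,0.13,0.27,-0.23,0.86,
soleus,0.26,1.50,0.29,0.98,
tibialis_anterior,0.062,-1.11,-0.19,1.09,
x_heel,,,,,0.0574
x_toe,,,,,0.0124
z_heel,,,,,0.15
z_toe,,,,,0.71
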