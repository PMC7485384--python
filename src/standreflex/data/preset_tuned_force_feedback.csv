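name,u0,g_ffb,g_lfb,l_off,value
iliopsoas,0.5165302197395292,2.2185471139367845,0.0,1.1,
gluteals,0.12764092918021508,-0.32021657987613417,0.0,1.1,
rectus_femoris,0.25778180020357266,1.015155835623729,0.0,1.1,
biceps_femoris_lh,0.43826628842937976,2.137473285469869,0.0,1.1,
biceps_femoris_sh,0.17896056802273932,-0.6210523631051058,0.0,1.1,
vastus,0.38674878560688875,-1.5807186663375778,0.0,1.1,
gastrocnemius,0.23125287623751917,0.08759936209909396,0.0,1.1,
soleus,0.6694533647311515,2.9035182890498317,0.0,1.1,
tibialis_anterior,0.3628332167822857,-2.543802946124217,0.0,1.1,
x_heel,,,,,0.09954305654660849
x_toe,,,,,0.09153820296291845
z_heel,,,,,0.2228943922696941
z_toe,,,,,0.2551459447461927
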