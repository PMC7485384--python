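name,u0,g_ffb,g_lfb,l_off,value
iliopsoas,0.44751551145242857,1.758683350399455,0.14564149528386108,0.940740002518809,
gluteals,0.0836071183139816,-0.1363813526030502,2.630917511783783,0.6759464204470143,
rectus_femoris,0.3175522632745283,1.0460906853120582,-1.6090107959832727,1.0070588443901018,
biceps_femoris_lh,0.305279922648079,1.9698674017563964,-1.5465306657316822,0.47716791720289414,
biceps_femoris_sh,0.14744293044133047,-0.9153588346391448,2.433490051027109,0.7553855323939733,
vastus,0.3093630993233946,-1.779824991356343,-0.7591073262259396,0.6387180645635986,
gastrocnemius,0.2470400212122329,-0.24476704625097445,1.0958387970170873,0.5608349383435556,
soleus,0.6850525026513636,2.1915694426802497,2.6317966809878524,0.9416876968404769,
tibialis_anterior,0.2885339153420796,-2.9431695242157425,-2.7049162429933196,0.322204944812613,
x_heel,,,,,0.09885357113367937
x_toe,,,,,0.09695226884935668
z_heel,,,,,0.22720045822944834
z_toe,,,,,0.23654271821794137
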