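phage_a,phage_b,single_a,single_a_censored,single_b,single_b_censored,mix,mix_censored
EPa11,EPa16,7.54e-6,0,1.33e-6,0,5.70e-6,0
EPa11,EPa17,7.54e-6,0,2.19e-7,0,2.63e-8,0
EPa11,EPa22,7.54e-6,0,3.42e-6,0,6.40e-6,0
EPa11,EPa24,7.54e-6,0,9.39e-6,0,8.07e-6,0
EPa11,EPa40,7.54e-6,0,2.53e-7,0,1.58e-6,0
EPa11,EPa43,7.54e-6,0,8.77e-9,1,8.77e-9,1
EPa16,EPa17,1.33e-6,0,2.19e-7,0,1.67e-7,0
EPa16,EPa22,1.33e-6,0,3.42e-6,0,2.98e-6,0
EPa16,EPa24,1.33e-6,0,9.39e-6,0,5.35e-6,0
EPa16,EPa40,1.33e-6,0,2.53e-7,0,1.01e-6,0
EPa16,EPa43,1.33e-6,0,8.77e-9,1,8.77e-9,1
EPa17,EPa22,2.19e-7,0,3.42e-6,0,4.39e-8,0
EPa17,EPa24,2.19e-7,0,9.39e-6,0,3.51e-8,0
EPa17,EPa40,2.19e-7,0,2.53e-7,0,8.77e-8,0
EPa17,EPa43,2.19e-7,0,8.77e-9,1,8.77e-9,1
EPa22,EPa24,3.42e-6,0,9.39e-6,0,6.93e-6,0
EPa22,EPa40,3.42e-6,0,2.53e-7,0,1.19e-5,0
EPa22,EPa43,3.42e-6,0,8.77e-9,1,8.77e-9,1
EPa24,EPa40,9.39e-6,0,2.53e-7,0,1.19e-5,0
EPa24,EPa43,9.39e-6,0,8.77e-9,1,8.77e-9,1
EPa40,EPa43,2.53e-7,0,8.77e-9,1,8.77e-9,1
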