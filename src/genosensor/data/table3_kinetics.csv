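panel,row_label,mutation_status,ka_wt_probe,kd_wt_probe,Kd_wt_probe,Ka_wt_probe,ka_mut_probe,kd_mut_probe,Kd_mut_probe,Ka_mut_probe
5370C>T,Target,synthetic,2.61e7,8.09e-3,3.11e-10,3.22e9,1.45e6,2.87e-4,1.98e-10,5.05e9
5370C>T,Patient 1,with mut.,5.40e3,1.36e-3,2.52e-7,3.97e6,6.62e5,3.04e-4,4.59e-10,2.18e9
5370C>T,Patient 2,with mut.,1.31e4,5.59e-3,4.27e-7,2.34e6,3.14e5,1.89e-4,6.02e-10,1.66e9
5370C>T,Patient 3,without mut.,1.44e7,7.25e-3,5.04e-10,1.98e9,7.53e3,6.41e-3,8.51e-7,1.18e6
5370C>T,Patient 4,without mut.,3.11e7,6.13e-3,1.97e-10,5.08e9,5.93e5,5.99e-3,1.01e-8,9.90e7
5382insC,Target,synthetic,1.71e6,1.21e-3,7.06e-10,1.42e9,9.72e7,4.26e-3,4.38e-11,2.28e10
5382insC,Patient 5,with mut.,6.80e2,7.62e-3,1.12e-5,8.93e4,3.84e8,5.31e-3,1.38e-11,7.25e10
5382insC,Patient 6,with mut.,1.19e2,3.25e-3,2.72e-5,3.68e4,2.33e6,1.04e-4,4.46e-11,2.24e10
5382insC,Patient 7,with mut.,2.33e2,9.82e-3,4.21e-5,2.38e4,3.64e8,7.82e-3,2.15e-11,4.65e10
5382insC,Patient 8,without mut.,5.04e6,3.21e-3,6.37e-10,1.57e9,1.51e2,3.26e-4,2.15e-6,4.65e5
c.4035delA,Target,synthetic,1.06e6,2.82e-4,2.66e-10,3.76e9,8.17e6,3.86e-4,4.72e-11,2.12e10
c.4035delA,Patient 9,with mut.,3.73e2,1.20e-3,3.21e-6,3.12e5,3.03e6,1.89e-4,6.24e-11,1.60e10
c.4035delA,Patient 10,with mut.,4.91e2,2.76e-3,5.62e-6,1.78e5,1.65e6,7.21e-4,4.37e-10,2.29e9
c.4035delA,Patient 11,without mut.,2.68e6,4.35e-4,1.62e-10,6.17e9,4.69e2,4.32e-3,9.21e-6,1.09e5
c.4035delA,Patient 12,without mut.,2.65e6,3.26e-4,1.23e-10,8.13e9,1.27e3,7.93e-3,6.24e-6,1.60e5
185delAG,Target,synthetic,2.04e5,1.46e-5,7.14e-11,1.40e10,4.22e6,5.23e-4,1.24e-10,8.06e9
185delAG,Patient 13,with mut.,4.68e2,2.33e-3,4.98e-6,2.01e5,2.65e6,3.19e-4,1.20e-10,8.33e9
185delAG,Patient 14,without mut.,2.97e5,1.73e-5,5.85e-11,1.71e10,3.43e3,5.63e-2,1.64e-5,6.10e4
185delAG,Patient 15,without mut.,3.02e5,3.45e-5,1.14e-10,8.77e9,8.81e2,6.27e-3,7.12e-6,1.40e5
185delAG,Patient 16,without mut.,2.93e5,2.97e-5,1.01e-10,9.90e9,4.22e3,6.19e-2,1.47e-5,6.80e4
3819del5GTAAA,Target,synthetic,2.32e6,4.58e-3,1.97e-9,5.08e8,1.05e7,7.21e-3,6.84e-10,1.46e9
3819del5GTAAA,Patient 17,with mut.,5.56e1,2.41e-3,4.33e-5,2.31e4,1.73e7,8.38e-3,4.84e-10,2.07e9
3819del5GTAAA,Patient 18,with mut.,1.51e3,4.85e-3,3.21e-6,3.12e5,3.81e7,6.72e-3,1.76e-10,5.68e9
3819del5GTAAA,Patient 19,with mut.,5.15e1,3.72e-3,7.21e-5,1.39e4,2.39e7,7.77e-3,3.24e-10,3.09e9
3819del5GTAAA,Patient 20,without mut.,2.58e7,5.31e-2,2.06e-9,4.85e8,1.14e1,4.25e-4,3.71e-5,2.70e4
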