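patient,rho1,rho2,tau,psi,alpha1,alpha2
1,1.22e-3,5.54e-3,5.82e-3,9.79e-1,5.13e-1,8.9e-2
2,6.65e-4,1.98e-3,2.09e-3,2.9e-1,2.2e-1,4e-2
3,1.26e-3,4.35e-3,2.89e-3,5.33e-1,3.5e-1,6e-2
4,8.26e-4,1.02e-2,8.9e-3,3.96e-1,4.98e-1,9.9e-2
5,6.24e-4,1.796e-3,1.69e-3,1.9e-1,2.55e-1,5.3e-2
6,9.4e-4,7.25e-3,9.64e-3,3.9e-1,2.68e-1,7.5e-2
7,5.7e-4,1.73e-3,2.57e-3,3.5e-1,3.88e-1,7.2e-2
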