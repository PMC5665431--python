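cluster,reference,time_gen,se_gen,p_admixture
Midland,C282,52.0,3.6,4.3E-17
Midland,C284,49.9,3.2,7.1E-36
Midland,C291,53.5,3.4,6.1E-25
Midland,C280,56.9,7.2,8.4E-10
Fukuoka,C282,46.5,3.9,2.0E-10
Fukuoka,C284,51.6,5.4,2.9E-14
Fukuoka,C291,50.6,6.8,1.4E-12
Fukuoka,C280,55.1,10.6,3.0E-05
Ehime,C282,50.5,10.0,7.3E-04
Ehime,C284,37.6,5.0,4.1E-13
Ehime,C291,47.8,7.2,2.9E-10
Ehime,C280,42.8,7.4,2.1E-03
Shimane 1,C282,58.9,13.1,3.3E-03
Shimane 1,C284,51.5,8.4,4.9E-02
Shimane 1,C291,58.0,8.8,5.6E-10
Shimane 1,C280,51.5,8.4,9.9E-09
Shimane 2,C282,33.8,8.3,1.9E-03
Shimane 2,C284,46.8,13.3,7.2E-03
Shimane 2,C291,44.7,11.0,5.9E-04
Shimane 2,C280,40.9,8.8,4.2E-05
Ryukyu 1,C282,38.1,2.2,7.2E-49
Ryukyu 1,C284,38.2,2.2,3.0E-64
Ryukyu 1,C291,39.3,1.9,1.9E-60
Ryukyu 1,C280,43.8,2.3,1.0E-69
Ryukyu 2,C282,43.1,2.5,2.0E-36
Ryukyu 2,C284,43.5,2.6,1.7E-50
Ryukyu 2,C291,41.4,3.1,7.1E-39
Ryukyu 2,C280,41.5,4.4,1.7E-20
Ryukyu 3,C282,47.1,9.2,4.1E-06
Ryukyu 3,C284,54.4,9.4,9.5E-08
Ryukyu 3,C291,53.1,8.1,8.4E-10
Ryukyu 3,C280,55.4,13.3,3.5E-04
Ryukyu 4,C282,43.2,8.2,3.3E-05
Ryukyu 4,C284,54.0,10.8,6.2E-06
Ryukyu 4,C291,54.8,10.7,3.3E-06
Ryukyu 4,C280,56.0,12.3,6.8E-05
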