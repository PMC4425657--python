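residue	side_mass	sigma	dr_ca	dr_nh	dr_co	sq_ca_prev	sq_co_prev	sq_nh_next	sq_ca_next	sq_co_prev2
A	1.00000000000000000e+00	2.65285463140657329e+00	1.53000000000000003e+00	2.44959367902551461e+00	2.49024863703417854e+00	2.38232048677746544e+00	2.49482048677746482e+00	2.23232048677746509e+00	2.38232048677746544e+00	2.49482048677746482e+00
C	3.13200000000000012e+00	3.16504789577633794e+00	1.94999999999999996e+00	2.80741209944253756e+00	2.84548003402674832e+00	2.57439296091612668e+00	2.68689296091612650e+00	2.42439296091612677e+00	2.57439296091612668e+00	2.68689296091612650e+00
D	3.85999999999999988e+00	3.22073671896232039e+00	2.20000000000000018e+00	3.02799230526170549e+00	3.06471562012786825e+00	2.59527626961087021e+00	2.70777626961087003e+00	2.44527626961087030e+00	2.59527626961087021e+00	2.70777626961087003e+00
E	4.79300000000000015e+00	3.71551557876877814e+00	2.64999999999999991e+00	3.43520768936232201e+00	3.46983965148756246e+00	2.78081834203829192e+00	2.89331834203829175e+00	2.63081834203829157e+00	2.78081834203829192e+00	2.89331834203829175e+00
F	6.06099999999999994e+00	4.39734017275286693e+00	3.00000000000000000e+00	3.75868280858239734e+00	3.79193914752472816e+00	3.03650256478232539e+00	3.14900256478232476e+00	2.88650256478232503e+00	3.03650256478232539e+00	3.14900256478232476e+00
G										
H	5.39400000000000013e+00	3.93624141314059184e+00	2.75000000000000000e+00	3.52711238138298055e+00	3.56133083134938166e+00	2.86359052992772201e+00	2.97609052992772183e+00	2.71359052992772209e+00	2.86359052992772201e+00	2.97609052992772183e+00
I	3.79899999999999993e+00	4.11798001055917151e+00	2.29999999999999982e+00	3.11746808846140233e+00	3.15369179146283951e+00	2.93174250395968938e+00	3.04424250395968965e+00	2.78174250395968947e+00	2.93174250395968938e+00	3.04424250395968965e+00
K	4.86500000000000021e+00	4.14230187391646965e+00	3.10000000000000009e+00	3.85195617023142578e+00	3.88485425490003600e+00	2.94086320271867629e+00	3.05336320271867612e+00	2.79086320271867594e+00	2.94086320271867629e+00	3.05336320271867612e+00
L	3.79899999999999993e+00	4.11798001055917151e+00	2.35000000000000009e+00	3.16244244587956702e+00	3.19842413653697122e+00	2.93174250395968938e+00	3.04424250395968965e+00	2.78174250395968947e+00	2.93174250395968938e+00	3.04424250395968965e+00
M	4.99800000000000022e+00	4.06845519401868927e+00	2.79999999999999982e+00	3.57322776937472408e+00	3.60724580975040476e+00	2.91317069775700865e+00	3.02567069775700848e+00	2.76317069775700830e+00	2.91317069775700865e+00	3.02567069775700848e+00
N	3.86200000000000010e+00	3.28268909554644228e+00	2.25000000000000000e+00	3.07264907557788725e+00	3.10911995167409394e+00	2.61850841082991614e+00	2.73100841082991597e+00	2.46850841082991579e+00	2.61850841082991614e+00	2.73100841082991597e+00
P	2.79899999999999993e+00	3.25407142056888032e+00	1.85000000000000009e+00	2.72060522940121974e+00	2.75925108331237423e+00	2.60777678271333002e+00	2.72027678271333029e+00	2.45777678271332967e+00	2.60777678271333002e+00	2.72027678271333029e+00
Q	4.79499999999999993e+00	3.79903812498162097e+00	2.70000000000000018e+00	3.48110425152415859e+00	3.51552730734345253e+00	2.81213929686810804e+00	2.92463929686810786e+00	2.66213929686810769e+00	2.81213929686810804e+00	2.92463929686810786e+00
R	6.72799999999999976e+00	4.20250722927912079e+00	3.54999999999999982e+00	4.27545094764445643e+00	4.30690120116476471e+00	2.96344021097967047e+00	3.07594021097967030e+00	2.81344021097967012e+00	2.96344021097967047e+00	3.07594021097967030e+00
S	2.06400000000000006e+00	2.66520803253588223e+00	1.69999999999999996e+00	2.59217823296713501e+00	2.63173543803969512e+00	2.38695301220095590e+00	2.49945301220095573e+00	2.23695301220095555e+00	2.38695301220095590e+00	2.49945301220095573e+00
T	2.99699999999999989e+00	3.32272583521093967e+00	1.94999999999999996e+00	2.80741209944253756e+00	2.84548003402674832e+00	2.63352218820410222e+00	2.74602218820410249e+00	2.48352218820410231e+00	2.63352218820410222e+00	2.74602218820410249e+00
V	2.86600000000000010e+00	3.74065302367307062e+00	1.94999999999999996e+00	2.80741209944253756e+00	2.84548003402674832e+00	2.79024488387740144e+00	2.90274488387740170e+00	2.64024488387740153e+00	2.79024488387740144e+00	2.90274488387740170e+00
W	8.65799999999999947e+00	4.78934570853393193e+00	3.35000000000000009e+00	4.08653166413912583e+00	4.11859415213805669e+00	3.18350464070022454e+00	3.29600464070022481e+00	3.03350464070022419e+00	3.18350464070022454e+00	3.29600464070022481e+00
Y	7.12600000000000033e+00	4.43873196920867219e+00	3.20000000000000018e+00	3.94555905027855980e+00	3.97811295278292265e+00	3.05202448845325236e+00	3.16452448845325174e+00	2.90202448845325200e+00	3.05202448845325236e+00	3.16452448845325174e+00
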