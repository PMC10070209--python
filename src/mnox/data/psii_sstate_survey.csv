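pdb_id,method,reported_s,m1_s,m1_ox,m2_s,m2_ox
3wu2,X-ray,1,-2,"III,III,III,II",-1,"III,IV,III,II"
4il6,X-ray,1,0,"III,IV,III,III",0,"III,IV,III,III"
4pj0,X-ray,1,-1,"III,IV,III,II",-2,"III,III,III,II"
4ub6,XFEL,1,0,"III,IV,III,III",1,"III,IV,IV,III"
4ub8,XFEL,1,0,"III,IV,III,III",0,"III,IV,III,III"
5b5e,X-ray,1,0,"III,IV,III,III",1,"III,IV,IV,III"
5b66,X-ray,1,0,"III,IV,III,III",0,"III,IV,IV,II"
5gth,XFEL,1,1,"III,IV,IV,III",1,"III,IV,IV,III"
5gti,XFEL,3,1,"III,IV,IV,III",1,"III,IV,IV,III"
5h2f,X-ray,1,-1,"III,III,III,III",-1,"III,IV,III,II"
5tis,XFEL,3,0,"III,IV,III,III",0,"III,III,IV,III"
5ws5,XFEL,1,1,"III,IV,IV,III",1,"III,IV,IV,III"
5ws6,XFEL,3,1,"III,IV,IV,III",1,"III,IV,IV,III"
5zzn,cryoEM,1,-1,"III,IV,III,II",-1,"III,IV,III,II"
6dhe,XFEL,1,1,"III,IV,IV,III",1,"III,IV,IV,III"
6dhf,XFEL,2,2,"III,IV,IV,IV",1,"III,IV,IV,III"
6dho,XFEL,3,2,"IV,IV,IV,III",1,"III,IV,IV,III"
6dhp,XFEL,0,3,"IV,IV,IV,IV",2,"III,IV,IV,IV"
6jlj,XFEL,1,1,"III,IV,IV,III",1,"III,IV,IV,III"
6jlk,XFEL,2,1,"III,IV,IV,III",1,"III,IV,IV,III"
6jll,XFEL,3,2,"IV,IV,IV,III",2,"IV,IV,IV,III"
6jlm,XFEL,1,1,"III,IV,IV,III",1,"III,IV,IV,III"
6jln,XFEL,2,0,"III,IV,III,III",1,"III,IV,IV,III"
6jlo,XFEL,3,0,"III,III,IV,III",1,"III,IV,IV,III"
6jlp,XFEL,0,1,"IV,IV,IV,II",1,"III,IV,IV,III"
6w1o,XFEL,1,1,"III,IV,IV,III",1,"III,IV,IV,III"
6w1p,XFEL,2,1,"III,IV,IV,III",1,"III,IV,IV,III"
6w1v,XFEL,3,3,"IV,IV,IV,IV",1,"III,IV,IV,III"
7cji,XFEL,1,1,"III,IV,IV,III",0,"III,IV,IV,II"
7cjj,XFEL,2,1,"III,IV,IV,III",1,"III,IV,IV,III"
7cou,XFEL,1,1,"III,IV,IV,III",0,"III,IV,IV,II"
7d1t,cryoEM,1,-4,"III,II,II,II",-4,"III,II,II,II"
7d1u,cryoEM,1,-2,"III,III,III,II",-2,"III,III,III,II"
7n8o,cryoEM,1,-5,"II,II,II,II",-5,"II,II,II,II"
7rcv,cryoEM,1,-5,"II,II,II,II",-5,"II,II,II,II"
7rf2,XFEL,1,2,"III,IV,IV,IV",1,"III,IV,IV,III"
7rf3,XFEL,2,1,"III,IV,IV,III",2,"III,IV,IV,IV"
7rf8,XFEL,3,2,"III,IV,IV,IV",1,"III,IV,IV,III"
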