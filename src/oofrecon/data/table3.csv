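dataset,energy,technique,local_2_2,global_2_2,global_3_2,median_dd
Abdomen-TG244,6X,VMAT,97.5,99.7,100.0,0.6
Abdomen-TG244,6X,IMRT,94.7,99.6,99.9,1.1
Abdomen-TG244,15X,VMAT,97.9,99.1,99.9,-0.3
Abdomen-TG244,15X,IMRT,95.0,98.4,99.7,0.2
Abdomen-TG244,10XFFF,VMAT,98.3,99.8,100.0,-0.6
Abdomen-TG244,10XFFF,IMRT,91.1,98.9,99.9,-1.1
HN-TG244,6X,VMAT,90.2,98.1,99.9,0.7
HN-TG244,6X,WFIMRT,83.7,93.4,99.5,1.0
HN-TG244,15X,VMAT,92.2,98.7,100.0,1.0
HN-TG244,15X,WFIMRT,85.2,95.8,99.4,1.6
HN-TG244,10XFFF,VMAT,90.3,95.9,99.5,-1.6
HN-TG244,10XFFF,WFIMRT,91.8,97.1,99.7,-0.9
Anal-TG244,6X,VMAT,82.7,93.3,99.3,2.5
Anal-TG244,6X,WFIMRT,75.5,84.1,93.2,3.1
Anal-TG244,15X,VMAT,87.3,96.5,99.8,2.3
Anal-TG244,15X,WFIMRT,78.2,87.1,94.9,2.9
Anal-TG244,10XFFF,VMAT,95.2,99.5,99.9,-0.5
Anal-TG244,10XFFF,WFIMRT,92.6,98.3,99.6,0.5
Cshape-TG119,6X,VMAT,87.0,96.7,99.1,2.3
Cshape-TG119,6X,IMRT,89.6,97.5,99.3,1.5
Cshape-TG119,15X,VMAT,91.3,98.8,99.7,1.6
Cshape-TG119,15X,IMRT,89.3,95.9,98.5,0.9
Cshape-TG119,10XFFF,VMAT,93.5,98.5,99.7,0.4
Cshape-TG119,10XFFF,IMRT,93.2,98.6,99.7,0.5
HN-TG119,6X,VMAT,94.8,99.2,99.9,1.3
HN-TG119,6X,IMRT,95.8,98.9,99.9,0.3
HN-TG119,15X,VMAT,94.6,98.9,99.8,0.9
HN-TG119,15X,IMRT,93.6,97.7,99.5,0.8
HN-TG119,10XFFF,VMAT,95.3,98.6,99.7,0.1
HN-TG119,10XFFF,IMRT,93.4,98.9,99.9,-0.7
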