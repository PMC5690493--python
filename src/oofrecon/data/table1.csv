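dataset,energy,technique,local_2_2,global_2_2,median_dd
Abdomen-TG244,6X,VMAT,100.0,100.0,0.2
Abdomen-TG244,6X,IMRT,98.2,100.0,0.3
Abdomen-TG244,15X,VMAT,100.0,100.0,-0.1
Abdomen-TG244,15X,IMRT,99.1,99.8,0.0
Abdomen-TG244,10XFFF,VMAT,95.9,96.6,-0.9
Abdomen-TG244,10XFFF,IMRT,97.5,99.2,-0.5
HN-TG244,6X,VMAT,96.2,98.3,0.4
HN-TG244,6X,WFIMRT,96.0,97.9,0.3
HN-TG244,15X,VMAT,98.7,99.6,-0.1
HN-TG244,15X,WFIMRT,99.2,99.9,-0.1
HN-TG244,10XFFF,VMAT,84.4,92.7,1.3
HN-TG244,10XFFF,WFIMRT,87.8,94.4,1.3
Anal-TG244,6X,VMAT,99.1,100.0,-0.1
Anal-TG244,6X,WFIMRT,94.7,97.1,-0.1
Anal-TG244,15X,VMAT,98.0,99.0,-0.6
Anal-TG244,15X,WFIMRT,91.8,96.8,-0.8
Anal-TG244,10XFFF,VMAT,93.3,98.5,0.7
Anal-TG244,10XFFF,WFIMRT,91.1,96.7,0.7
Cshape-TG119,6X,VMAT,98.0,99.5,-0.1
Cshape-TG119,6X,IMRT,98.4,99.4,0.4
Cshape-TG119,15X,VMAT,98.9,99.8,-0.3
Cshape-TG119,15X,IMRT,99.1,99.2,0.6
Cshape-TG119,10XFFF,VMAT,97.3,99.0,-0.7
Cshape-TG119,10XFFF,IMRT,99.8,100.0,-0.5
HN-TG119,6X,VMAT,97.5,99.4,-0.4
HN-TG119,6X,IMRT,97.3,99.7,0.5
HN-TG119,15X,VMAT,98.2,99.2,-0.3
HN-TG119,15X,IMRT,98.6,99.8,0.4
HN-TG119,10XFFF,VMAT,97.7,98.8,-0.4
HN-TG119,10XFFF,IMRT,99.2,100.0,0.0
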